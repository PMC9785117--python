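"""Synthetic cohort and LC-HRMS-style feature-table generators.

The study design emulated here is a cross-sectional serum-metabolomics cohort:
~138 apparently healthy adults aged 20-70 (about 56% male, non-obese,
BMI < 30 kg/m^2), profiled for clinical markers and ~175 metabolite variables
(47 NMR-quantified compounds plus 128 LC-HRMS features).  A subset of
variables carries a BMI-adjusted age association of magnitude ~0.21-0.37
(branched-chain amino acids, tryptophan, asparagine and 3-hydroxyisobutyrate
declining with age; aspartate, ornithine and the lipid/glucose clinical panel
rising), and the latent age trend of the aging panel is piecewise linear with
a planted hinge ("aging metabolism breakpoint") so that the downstream
breakpoint detector has a known ground truth.

Concentrations are generated on the log scale (log-normal noise), which keeps
them strictly positive, right-skewed, and gives the Box-Cox lambda search a
non-trivial optimum.  Per-variable age effects are calibrated so that the
BMI-partialled Pearson correlation of the log concentration with age matches a
target value in expectation; alternatively literal hinge slopes can be used
for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "VariableSpec",
    "BMIModel",
    "GeneratorConfig",
    "CohortTable",
    "FeatureTable",
    "generate_cohort",
    "split_cohort",
    "generate_feature_table",
    "default_variables",
    "recovery_config",
    "AGING_PANEL",
]

# Metabolites entering the PCA / breakpoint analysis (plus BMI): the panel the
# screening and enrichment stages converge on.
AGING_PANEL = (
    "valine",
    "leucine",
    "isoleucine",
    "3_hydroxyisobutyrate",
    "asparagine",
    "aspartate",
    "ornithine",
)


@dataclass
class VariableSpec:
    """One generated clinical-marker or metabolite variable.

    The latent log-concentration model is

        log y = baseline + trend(age) + factor_loading * eta + noise_sd * eps
                + sex_effect * male

    where ``trend`` is a hinge that is continuous at the breakpoint age tau:
    ``pre_slope * (age - tau)`` before tau and ``post_slope * (age - tau)``
    after, and ``eta`` is a cohort-wide shared latent factor (one draw per
    subject) that induces the strong mutual correlation of, e.g., the
    branched-chain amino acids.  If ``target_partial_r`` is set, the trend is
    rescaled (keeping its hinge shape) so that the BMI-partialled correlation
    of log y with age equals the target in expectation; the literal slope
    magnitudes then only fix the pre/post shape ratio.
    """

    name: str
    role: str = "metabolite"  # "metabolite" or "clinical"
    baseline: float = 0.0  # log-scale level at age == breakpoint_age
    target_partial_r: float | None = None
    pre_slope: float = 0.0  # log-units per year before the breakpoint
    post_slope: float = 0.0  # log-units per year after the breakpoint
    noise_sd: float = 0.25  # idiosyncratic log-scale SD
    factor_loading: float = 0.0  # loading on the shared latent factor
    sex_effect: float = 0.0  # additive log-scale shift for males (default none)


@dataclass
class BMIModel:
    """Linear BMI-vs-age model with truncation below the non-obese bound.

    Defaults give a BMI-age correlation of ~0.225 and a median BMI of
    ~24.8 kg/m^2, with the cohort restricted to BMI < 30 kg/m^2.
    """

    intercept: float = 23.2  # kg/m^2 at age 45
    slope: float = 0.035  # kg/m^2 per year
    residual_sd: float = 2.2
    upper: float = 30.0


def _clinical_specs() -> list[VariableSpec]:
    # Positive age associations of the lipid/glucose panel; remaining markers null.
    pos = {
        "total_cholesterol": (188.0, 0.370),
        "hdl": (52.0, 0.219),
        "ldl": (113.0, 0.243),
        "vldl": (19.0, 0.214),
        "triacylglyceride": (93.0, 0.212),
        "glucose": (90.8, 0.213),
    }
    null = {"uric_acid": 5.1, "urea": 31.0, "creatinine": 0.88, "hs_crp": 0.62}
    specs = [
        VariableSpec(
            name=n,
            role="clinical",
            baseline=float(np.log(level)),
            target_partial_r=r,
            pre_slope=0.004,
            post_slope=0.004,
            noise_sd=0.20,
        )
        for n, (level, r) in pos.items()
    ]
    specs += [
        VariableSpec(name=n, role="clinical", baseline=float(np.log(level)), noise_sd=0.25)
        for n, level in null.items()
    ]
    return specs


_NMR_NULL_NAMES = [
    "alanine", "glutamine", "glutamate", "glycine", "histidine", "lysine",
    "methionine", "phenylalanine", "proline", "serine", "threonine", "tyrosine",
    "creatine", "carnitine", "acetate", "acetone", "acetoacetate",
    "3_hydroxybutyrate", "lactate", "pyruvate", "citrate", "succinate",
    "formate", "fumarate", "glycerol", "choline", "betaine",
    "trimethylamine_n_oxide", "dimethylamine", "methanol", "mannose",
    "myo_inositol", "taurine", "sarcosine", "isobutyrate", "2_oxoisocaproate",
    "2_aminobutyrate", "ornithine_precursor", "dimethylglycine", "threonate",
]


def _nmr_specs() -> list[VariableSpec]:
    # Declining panel: BCAAs, 3-hydroxyisobutyrate, asparagine (hinged decline,
    # steeper after the breakpoint); rising urea-cycle pair (aspartate,
    # ornithine).  BCAA-family members share a latent factor so that they
    # dominate PC1, as branched-chain amino acids do in serum.
    neg = {
        "3_hydroxyisobutyrate": -0.257,
        "asparagine": -0.214,
        "isoleucine": -0.280,
        "leucine": -0.215,
        "valine": -0.225,
    }
    pos = {"aspartate": 0.237, "ornithine": 0.269}
    bcaa_family = {"valine", "leucine", "isoleucine", "3_hydroxyisobutyrate"}
    specs = [
        VariableSpec(
            name=n,
            baseline=float(np.log(0.15)),
            target_partial_r=r,
            pre_slope=0.004,
            post_slope=-0.010,
            noise_sd=0.25,
            factor_loading=0.25 if n in bcaa_family else 0.0,
        )
        for n, r in neg.items()
    ]
    specs += [
        VariableSpec(
            name=n,
            baseline=float(np.log(0.08)),
            target_partial_r=r,
            pre_slope=-0.002,
            post_slope=0.008,
            noise_sd=0.25,
        )
        for n, r in pos.items()
    ]
    specs += [
        VariableSpec(name=n, baseline=float(np.log(0.1)), noise_sd=0.25)
        for n in _NMR_NULL_NAMES
    ]
    return specs


def _lc_specs() -> list[VariableSpec]:
    signal = {
        "tryptophan": -0.285,
        "unknown_compound_1": -0.24,
        "unknown_compound_2": -0.25,
        "unknown_compound_3": -0.22,
    }
    specs = [
        VariableSpec(
            name=n,
            baseline=11.5,
            target_partial_r=r,
            pre_slope=0.003,
            post_slope=-0.008,
            noise_sd=0.35,
        )
        for n, r in signal.items()
    ]
    specs += [
        VariableSpec(name=f"lc_feature_{i:03d}", baseline=11.5, noise_sd=0.35)
        for i in range(5, 129)
    ]
    return specs


def default_variables() -> list[VariableSpec]:
    """Paper-structured default variable set: 10 clinical markers, 47 NMR
    metabolites (7 with age signal) and 128 LC-HRMS features (4 with signal)."""
    return _clinical_specs() + _nmr_specs() + _lc_specs()


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort draw."""

    n_subjects: int = 138
    age_range: tuple[float, float] = (20.0, 70.0)
    male_fraction: float = 0.56
    breakpoint_age: float = 32.0
    variables: list[VariableSpec] = field(default_factory=default_variables)
    bmi_model: BMIModel = field(default_factory=BMIModel)
    missing_rate: float = 0.02
    seed: int = 0
    pca_panel: tuple[str, ...] = AGING_PANEL

    def validate(self) -> None:
        if self.n_subjects < 9:
            raise ConfigurationError(
                "n_subjects: need at least 9 subjects (3x minimum breakpoint segment)"
            )
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range: interval is empty")
        if not 0.0 <= self.missing_rate < 0.1:
            raise ConfigurationError("missing_rate: must be in [0, 0.1)")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction: must be in [0, 1]")
        names = [v.name for v in self.variables]
        if len(names) != len(set(names)):
            raise ConfigurationError("variables: duplicate variable names")
        for v in self.variables:
            if v.noise_sd < 0:
                raise ConfigurationError(f"noise_sd: negative for variable {v.name}")
            if v.target_partial_r is not None and not -1.0 < v.target_partial_r < 1.0:
                raise ConfigurationError(
                    f"target_partial_r: out of (-1, 1) for variable {v.name}"
                )
            if v.role not in ("metabolite", "clinical"):
                raise ConfigurationError(f"role: unknown role {v.role!r} for {v.name}")
        if self.bmi_model.residual_sd <= 0:
            raise ConfigurationError("bmi_model.residual_sd: must be positive")


@dataclass
class CohortTable:
    """Subjects x variables table with per-variable roles and split labels.

    ``data`` holds age/sex/bmi plus all generated variables (NaN where
    missing); ``mask`` is True where a cell is observed; ``roles`` maps every
    column to one of age|sex|bmi|clinical|metabolite; ``split`` holds
    train/test labels once :func:`split_cohort` has run.
    """

    data: pd.DataFrame
    roles: dict[str, str]
    mask: pd.DataFrame
    split: pd.Series | None = None

    def variables(self, *roles: str) -> list[str]:
        """Column names whose role is one of ``roles`` (insertion order)."""
        return [c for c in self.data.columns if self.roles[c] in roles]

    def arm(self, label: str) -> "CohortTable":
        """Subset to one split arm ('train' or 'test')."""
        if self.split is None:
            raise DataError("cohort has no split labels; run split_cohort first")
        idx = self.split[self.split == label].index
        return CohortTable(
            data=self.data.loc[idx].copy(),
            roles=dict(self.roles),
            mask=self.mask.loc[idx].copy(),
            split=self.split.loc[idx].copy(),
        )

    def copy(self) -> "CohortTable":
        return CohortTable(
            data=self.data.copy(),
            roles=dict(self.roles),
            mask=self.mask.copy(),
            split=None if self.split is None else self.split.copy(),
        )


def _hinge(ages: np.ndarray, tau: float, pre: float, post: float) -> np.ndarray:
    """Piecewise-linear trend, continuous and equal to 0 at the hinge age."""
    return np.where(ages < tau, pre * (ages - tau), post * (ages - tau))


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of y on covariates plus intercept."""
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw one cohort from the generator model.

    Ages are uniform on the configured range; BMI follows the linear-in-age
    model truncated below the non-obese bound by resampling; each variable's
    log concentration follows its :class:`VariableSpec`.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.age_range

    ages = rng.uniform(lo, hi, size=n)
    sex = (rng.random(n) < config.male_fraction).astype(int)  # 1 = male

    bm = config.bmi_model
    bmi = bm.intercept + bm.slope * (ages - 45.0) + rng.normal(0.0, bm.residual_sd, size=n)
    # resample values at or above the truncation bound
    for _ in range(100):
        bad = bmi >= bm.upper
        if not bad.any():
            break
        bmi[bad] = (
            bm.intercept
            + bm.slope * (ages[bad] - 45.0)
            + rng.normal(0.0, bm.residual_sd, size=int(bad.sum()))
        )
    np.clip(bmi, None, bm.upper - 1e-6, out=bmi)

    age_resid = _residualize(ages, bmi)
    age_resid_sd = age_resid.std(ddof=1)
    eta = rng.normal(0.0, 1.0, size=n)  # shared latent factor

    columns: dict[str, np.ndarray] = {"age": ages, "sex": sex.astype(float), "bmi": bmi}
    roles: dict[str, str] = {"age": "age", "sex": "sex", "bmi": "bmi"}

    for spec in config.variables:
        trend = _hinge(ages, config.breakpoint_age, spec.pre_slope, spec.post_slope)
        if spec.target_partial_r is not None:
            r = spec.target_partial_r
            shape = trend
            if np.allclose(shape, shape[0]):
                shape = ages - ages.mean()  # flat hinge: fall back to linear age
            g = _residualize(shape, bmi)
            g_sd = g.std(ddof=1)
            if g_sd <= 0:
                raise ConfigurationError(
                    f"pre_slope/post_slope: trend for {spec.name} is degenerate"
                )
            g = g / g_sd
            rho = float(np.dot(g, age_resid) / ((n - 1) * age_resid_sd))
            if abs(r) >= abs(rho):
                raise ConfigurationError(
                    f"target_partial_r: |{r}| unattainable for {spec.name}; "
                    f"hinge shape limits |r| to {abs(rho):.3f}"
                )
            q = r / rho
            noise_total = float(np.hypot(spec.factor_loading, spec.noise_sd))
            if noise_total == 0.0:
                trend_term = np.sign(q) * g
            else:
                trend_term = (q / np.sqrt(1.0 - q * q)) * noise_total * g
        else:
            trend_term = trend
        logy = (
            spec.baseline
            + trend_term
            + spec.factor_loading * eta
            + spec.sex_effect * sex
            + (rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0)
        )
        columns[spec.name] = np.exp(logy)
        roles[spec.name] = spec.role

    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    data = pd.DataFrame(columns, index=pd.Index(subject_ids, name="subject_id"))
    mask = pd.DataFrame(True, index=data.index, columns=data.columns)

    if config.missing_rate > 0:
        value_cols = [c for c in data.columns if roles[c] in ("clinical", "metabolite")]
        miss = rng.random((n, len(value_cols))) < config.missing_rate
        # keep at least 2 observed values per variable (imputation precondition)
        for j, c in enumerate(value_cols):
            if miss[:, j].sum() > n - 2:
                miss[:, j] = False
        mvals = data[value_cols].to_numpy()
        mvals[miss] = np.nan
        data[value_cols] = mvals
        mask[value_cols] = ~miss

    return CohortTable(data=data, roles=roles, mask=mask)


def split_cohort(table: CohortTable, train_fraction: float, seed: int) -> CohortTable:
    """Randomly assign subjects to train/test arms without replacement.

    The train arm gets ``round(train_fraction * n)`` subjects (105 of 138 at
    the study's ~75% fraction).  Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction: must be in (0, 1)")
    n = len(table.data)
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n - n_train < 2:
        raise DataError(
            f"split leaves an arm with fewer than 2 subjects ({n_train}/{n - n_train})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train:]] = "test"
    out = table.copy()
    out.split = pd.Series(labels, index=table.data.index, name="split")
    return out


# ---------------------------------------------------------------------------
# LC-HRMS-style feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Features x injections intensity matrix with injection metadata.

    ``intensities`` rows are features, columns are injection identifiers; NaN
    marks a missing (undetected) cell.  ``injection_class`` tags each
    injection as sample/blank/qc and ``injection_order`` gives its 1-based run
    position.  ``true_retained`` (generator output only) lists the features
    constructed to pass all inclusion filters.
    """

    intensities: pd.DataFrame
    injection_class: pd.Series
    injection_order: pd.Series
    true_retained: list[str] | None = None

    def validate(self) -> None:
        order = np.sort(self.injection_order.to_numpy())
        if not np.array_equal(order, np.arange(1, len(order) + 1)):
            raise DataError("injection_order: not a permutation of 1..n_injections")
        if (self.injection_class == "sample").sum() == 0:
            raise DataError("injection_class: no sample injections")
        vals = self.intensities.to_numpy()
        if np.nanmin(vals) < 0:
            raise DataError("intensities: negative intensity present")


def generate_feature_table(
    n_features: int,
    n_samples: int,
    n_blanks: int,
    n_qc: int,
    drift_amplitude: float,
    seed: int,
    *,
    qc_cv: float = 0.05,
    blank_fraction: float = 0.01,
    sample_cv: float = 0.40,
    n_fail_blank: int = 0,
    n_fail_cv: int = 0,
    n_fail_missing: int = 0,
    fail_blank_fraction: float = 0.5,
    fail_missing_fraction: float = 0.25,
) -> FeatureTable:
    """Generate a feature table with known filter ground truth.

    ``n_qc`` counts QC *groups*; each group is injected in triplicate, so the
    table carries ``3 * n_qc`` QC injections spread evenly across the run.
    A smooth multiplicative drift ``1 + A sin(2 pi (o-1)/(N-1))`` of amplitude
    ``A = drift_amplitude`` acts on every injection.  The first
    ``n_fail_blank`` features get blank signal at ``fail_blank_fraction`` of
    the sample level, the next ``n_fail_cv`` get a deterministic spread of QC
    group factors guaranteeing CV% far above any reasonable threshold, and the
    next ``n_fail_missing`` get ``fail_missing_fraction`` of their sample
    cells deleted; the disjoint remainder passes all three rules.
    """
    for name, val in (
        ("n_features", n_features),
        ("n_samples", n_samples),
        ("n_blanks", n_blanks),
        ("n_qc", n_qc),
    ):
        if val < 1:
            raise ConfigurationError(f"{name}: must be >= 1")
    if n_fail_blank + n_fail_cv + n_fail_missing > n_features:
        raise ConfigurationError("failure counts exceed n_features")
    if not 0.0 <= drift_amplitude < 1.0:
        raise ConfigurationError("drift_amplitude: must be in [0, 1)")

    if n_qc > n_samples:
        raise ConfigurationError("n_qc: cannot exceed n_samples (QC groups are spread between samples)")

    rng = np.random.default_rng(seed)
    n_qc_inj = 3 * n_qc
    n_inj = n_samples + n_blanks + n_qc_inj

    # Run layout: blanks first, then samples with QC triplets spread evenly.
    classes = ["blank"] * n_blanks
    qc_positions = set(np.linspace(0, n_samples, n_qc, endpoint=False).astype(int).tolist())
    for pos in range(n_samples):
        if pos in qc_positions:
            classes += ["qc"] * 3
        classes.append("sample")
    assert len(classes) == n_inj

    inj_ids = [f"inj{i + 1:03d}" for i in range(n_inj)]
    inj_class = pd.Series(classes, index=inj_ids, name="injection_class")
    inj_order = pd.Series(np.arange(1, n_inj + 1), index=inj_ids, name="injection_order")

    order = inj_order.to_numpy(dtype=float)
    if n_inj > 1:
        drift = 1.0 + drift_amplitude * np.sin(2.0 * np.pi * (order - 1) / (n_inj - 1))
    else:
        drift = np.ones(1)

    is_sample = (inj_class == "sample").to_numpy()
    is_blank = (inj_class == "blank").to_numpy()
    is_qc = (inj_class == "qc").to_numpy()
    qc_group = np.cumsum(is_qc)  # 1..n_qc_inj over qc positions
    qc_group_of = (qc_group - 1) // 3  # group index per qc injection

    feat_ids = [f"F{i + 1:03d}" for i in range(n_features)]
    base = rng.lognormal(mean=np.log(1e5), sigma=0.5, size=n_features)
    X = np.full((n_features, n_inj), np.nan)

    fail_blank = set(range(n_fail_blank))
    fail_cv = set(range(n_fail_blank, n_fail_blank + n_fail_cv))
    fail_missing = set(
        range(n_fail_blank + n_fail_cv, n_fail_blank + n_fail_cv + n_fail_missing)
    )
    # Deterministic QC group factors spanning ~60% CV for CV-failing features.
    cv_fail_factors = np.array([0.5, 1.0, 1.9])

    for i in range(n_features):
        bfrac = fail_blank_fraction if i in fail_blank else blank_fraction
        X[i, is_blank] = (
            base[i]
            * bfrac
            * drift[is_blank]
            * np.exp(rng.normal(0.0, 0.05, size=is_blank.sum()))
        )
        X[i, is_sample] = (
            base[i]
            * drift[is_sample]
            * np.exp(rng.normal(0.0, sample_cv, size=is_sample.sum()))
        )
        qc_noise = (
            np.exp(rng.normal(0.0, qc_cv, size=is_qc.sum()))
            if qc_cv > 0
            else np.ones(is_qc.sum())
        )
        group_factor = np.ones(is_qc.sum())
        if i in fail_cv:
            group_factor = cv_fail_factors[qc_group_of[is_qc] % 3]
        X[i, is_qc] = base[i] * drift[is_qc] * group_factor * qc_noise
        if i in fail_missing:
            sample_idx = np.flatnonzero(is_sample)
            k = max(1, int(np.ceil(fail_missing_fraction * len(sample_idx))))
            drop = rng.choice(sample_idx, size=k, replace=False)
            X[i, drop] = np.nan

    failing = fail_blank | fail_cv | fail_missing
    retained = [feat_ids[i] for i in range(n_features) if i not in failing]
    table = FeatureTable(
        intensities=pd.DataFrame(
            X, index=pd.Index(feat_ids, name="feature_id"), columns=inj_ids
        ),
        injection_class=inj_class,
        injection_order=inj_order,
        true_retained=retained,
    )
    table.validate()
    return table


def recovery_config(
    breakpoint_age: float,
    noise_scale: float = 1.0,
    seed: int = 0,
    n_subjects: int = 105,
) -> GeneratorConfig:
    """Generator configuration for breakpoint parameter-recovery studies.

    Uses the aging panel with literal hinge slopes (no correlation
    calibration) so that scaling ``noise_scale`` moves the signal-to-noise
    ratio.  The amino-acid panel follows a peak profile — rising 0.4%/yr up
    to the hinge (lean mass accrues until its third-decade peak) and falling
    1%/yr afterwards — while the urea-cycle pair mirrors it (-0.2%/yr then
    +0.8%/yr).  The slope change at the hinge is what the breakpoint detector
    estimates.  At ``noise_scale=1`` each metabolite carries 25%
    idiosyncratic CV plus a shared-factor CV of 15% — moderate biological
    noise for serum metabolites.
    """
    decline = ("valine", "leucine", "isoleucine", "3_hydroxyisobutyrate", "asparagine")
    rise = ("aspartate", "ornithine")
    variables = [
        VariableSpec(
            name=n,
            baseline=float(np.log(0.15)),
            pre_slope=0.004,
            post_slope=-0.010,
            noise_sd=0.25 * noise_scale,
            factor_loading=0.15 * noise_scale,
        )
        for n in decline
    ] + [
        VariableSpec(
            name=n,
            baseline=float(np.log(0.08)),
            pre_slope=-0.002,
            post_slope=0.008,
            noise_sd=0.25 * noise_scale,
        )
        for n in rise
    ]
    return GeneratorConfig(
        n_subjects=n_subjects,
        breakpoint_age=breakpoint_age,
        variables=variables,
        bmi_model=BMIModel(residual_sd=max(2.2 * noise_scale, 1e-9)),
        missing_rate=0.0,
        seed=seed,
    )
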