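"""Metabolite-set over-representation analysis (hypergeometric ORA).

Given a query set of metabolites (here: the variables surviving the
age-association screen) and a pathway library, each pathway is tested with
the one-sided upper-tail hypergeometric test: drawing ``query_size``
metabolites from a universe of ``universe_size`` of which ``pathway_size``
belong to the pathway, the p-value is P(X >= hits).  The enrichment ratio is
hits / expected hits with expected = query_size * pathway_size /
universe_size.  The background universe is the union of the library's
members.  A small synthetic SMPDB-style toy library is bundled for pipelines
without an external GMT file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = ["PathwayLibrary", "read_gmt", "toy_library", "ora_test"]


@dataclass
class PathwayLibrary:
    """Named metabolite sets plus the background universe (their union)."""

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)


def _parse_gmt(lines, source: str) -> PathwayLibrary:
    pathways: dict[str, frozenset[str]] = {}
    n_lines = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        n_lines += 1
        parts = line.split("\t")
        if len(parts) < 3:
            raise DataError(
                f"{source}:{lineno}: malformed GMT line (need name, description, >=1 member)"
            )
        name = parts[0].strip()
        members = frozenset(m.strip() for m in parts[2:] if m.strip())
        if not name or not members:
            raise DataError(f"{source}:{lineno}: empty pathway name or member list")
        if name in pathways:
            raise DataError(f"{source}:{lineno}: duplicate pathway name {name!r}")
        pathways[name] = members
    if not pathways:
        raise DataError(f"{source}: empty GMT file")
    universe = frozenset().union(*pathways.values())
    return PathwayLibrary(pathways=pathways, universe=universe)


def read_gmt(path: str | Path) -> PathwayLibrary:
    """Read a GMT file (name, description, tab-separated members per line)."""
    path = Path(path)
    with path.open() as fh:
        return _parse_gmt(fh, str(path))


def toy_library() -> PathwayLibrary:
    """The bundled synthetic SMPDB-style toy pathway library."""
    text = resources.files("metaboaging.data").joinpath("toy_smpdb.gmt").read_text()
    return _parse_gmt(text.splitlines(), "toy_smpdb.gmt")


def ora_test(query: set[str] | list[str], library: PathwayLibrary) -> tuple[pd.DataFrame, int]:
    """Over-representation test of the query set against every pathway.

    Query members absent from the library universe are dropped (unknown
    compounds cannot map to pathways); their count is returned alongside the
    record table.  Records carry hits, pathway/query/universe sizes, expected
    hits, enrichment ratio, the upper-tail hypergeometric p and its BH
    adjustment across pathways, sorted by p then pathway name.
    """
    query_set = set(query)
    mapped = query_set & library.universe
    n_dropped = len(query_set) - len(mapped)
    if not mapped:
        raise DataError("ora_test: no query members map to the library universe")

    M = len(library.universe)
    N = len(mapped)
    rows = []
    for name, members in library.pathways.items():
        K = len(members)
        hits = len(mapped & members)
        expected = N * K / M
        p = float(stats.hypergeom.sf(hits - 1, M, K, N))
        rows.append(
            {
                "pathway": name,
                "hits": hits,
                "pathway_size": K,
                "query_size": N,
                "universe_size": M,
                "expected": expected,
                "enrichment_ratio": hits / expected if expected > 0 else np.nan,
                "p_hyper": min(p, 1.0),
            }
        )
    records = pd.DataFrame(rows).set_index("pathway")
    records["p_fdr"] = multipletests(records["p_hyper"].to_numpy(), method="fdr_bh")[1]
    records = records.sort_values(["p_hyper", "pathway"], kind="mergesort")
    return records, n_dropped
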