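"""Fisher's-exact pathway enrichment of microRNA target-gene sets.

Given a set of microRNAs of interest, their target genes (user-supplied
two-column map) are pooled and each pathway in a user-supplied GMT file is
tested for over-representation of those targets against a user-supplied
background universe with a one-sided Fisher's exact test.  No pathway or
target content is bundled: predicted-target databases are versioned external
resources and must be provided as files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats


@dataclass
class GeneSetDB:
    """Pathway definitions, miR->target maps, and the background universe."""

    pathways: dict[str, set[str]]
    targets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("background gene universe must be nonempty")
        for name, genes in self.pathways.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(f"pathway {name!r} has genes outside the universe: {sorted(extra)[:5]}")
        for mir, genes in self.targets.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(f"miR {mir!r} has target genes outside the universe: {sorted(extra)[:5]}")


@dataclass
class EnrichmentResult:
    pathway: str
    overlap: int
    p_value: float
    contributing_mirs: list[str] = field(default_factory=list)
    overlapping_genes: list[str] = field(default_factory=list)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: tab-separated name, description, member genes."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = {g for g in parts[2:] if g}
    return out


def read_target_map(path) -> dict[str, set[str]]:
    """Read a two-column CSV (mir, gene) into a miR -> target-set map."""
    df = pd.read_csv(path)
    mir_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for mir, g in df.groupby(mir_col):
        out[str(mir)] = set(g[gene_col].astype(str))
    return out


def fisher_enrichment(
    mirs: list[str],
    db: GeneSetDB,
    per_mir: bool = False,
) -> list[EnrichmentResult]:
    """Rank pathways by one-sided Fisher's exact enrichment p-value.

    By default the target genes of all given miRs are pooled into one query
    set; with ``per_mir=True`` each miR is tested separately and results are
    concatenated.  The 2x2 table for a pathway P and query set Q over
    universe U is (|P & Q|, |P - Q|, |Q - P|, |U - P - Q|).
    """
    missing = [m for m in mirs if m not in db.targets]
    if missing:
        raise KeyError(f"miRs absent from the target map: {missing}")

    queries: list[tuple[list[str], set[str]]]
    if per_mir:
        queries = [([m], db.targets[m]) for m in mirs]
    else:
        union: set[str] = set()
        for m in mirs:
            union |= db.targets[m]
        queries = [(list(mirs), union)]

    results: list[EnrichmentResult] = []
    for query_mirs, query in queries:
        for name in sorted(db.pathways):
            genes = db.pathways[name]
            a = len(genes & query)
            b = len(genes - query)
            c = len(query - genes)
            d = len(db.universe) - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            contributing = [m for m in query_mirs if db.targets[m] & genes]
            results.append(
                EnrichmentResult(
                    pathway=name,
                    overlap=a,
                    p_value=float(p),
                    contributing_mirs=contributing,
                    overlapping_genes=sorted(genes & query),
                )
            )
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "overlap": [r.overlap for r in results],
            "p_value": [r.p_value for r in results],
            "contributing_mirs": [";".join(r.contributing_mirs) for r in results],
            "overlapping_genes": [";".join(r.overlapping_genes) for r in results],
        }
    )
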