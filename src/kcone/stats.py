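"""Differential metabolite statistics and pathway over-representation.

Concentrations are compared on the log scale with a two-sided Welch t-test
per metabolite; a metabolite is called significant when the p-value is below
``alpha`` AND the absolute log2 fold change exceeds ``lfc_min``.  Pathway
over-representation uses the upper-tail hypergeometric test against the set
of measured metabolites, with Holm (family-wise) and Benjamini-Hochberg
(FDR) corrections; a pathway is enriched when both adjusted values are below
their thresholds.  Cross-cell-line intersection then isolates the shared
metabolic signature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConcentrationTable",
    "DiffMetaboliteRecord",
    "PathwaySet",
    "EnrichmentRecord",
    "differential_metabolites",
    "ora",
    "intersect_enrichment",
    "intersect_significant_metabolites",
    "read_gmt",
    "write_gmt",
    "diff_records_to_frame",
    "enrichment_records_to_frame",
]


@dataclass(frozen=True)
class ConcentrationTable:
    """Metabolite x replicate matrix of strictly positive concentrations."""

    condition: str
    values: pd.DataFrame  # index: metabolite ids, columns: replicate labels

    def __post_init__(self) -> None:
        if self.values.shape[1] < 1:
            raise ValueError("need at least one replicate column")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate metabolite ids")
        if not (self.values.to_numpy(dtype=float) > 0).all():
            raise ValueError("concentrations must be strictly positive")

    @property
    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def replicate(self, i: int) -> pd.Series:
        return self.values.iloc[:, i].astype(float)

    def mean_profile(self) -> pd.Series:
        """Geometric mean across replicates (natural scale)."""
        return np.exp(np.log(self.values.astype(float)).mean(axis=1))

    @classmethod
    def from_tsv(cls, path, condition: str | None = None) -> "ConcentrationTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(condition=condition or str(path), values=df)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="metabolite")


@dataclass(frozen=True)
class DiffMetaboliteRecord:
    metabolite_id: str
    log2_fc: float  # mean log2(B / A)
    p_value: float  # NaN when undefined (fewer than 2 replicates)
    significant: bool


@dataclass(frozen=True)
class PathwaySet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentRecord:
    pathway: str
    k: int  # overlap of selected with the set
    K: int  # set size within background
    n: int  # selected size
    N: int  # background size
    p_hyper: float
    p_holm: float
    fdr: float
    enriched: bool


def differential_metabolites(
    table_a: ConcentrationTable,
    table_b: ConcentrationTable,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> list[DiffMetaboliteRecord]:
    """Per-metabolite log2 fold change (B over A) and Welch t-test on logs.

    With fewer than two replicates in either condition the p-value is
    undefined (NaN) and the metabolite is never called significant.  A
    metabolite with zero variance and equal means in both conditions gets
    p = 1 (no evidence of change).
    """
    if tuple(table_a.metabolite_ids) != tuple(table_b.metabolite_ids):
        raise ValueError("tables must share the same metabolite ids in the same order")
    la = np.log(table_a.values.to_numpy(dtype=float))
    lb = np.log(table_b.values.to_numpy(dtype=float))
    lfc = (lb.mean(axis=1) - la.mean(axis=1)) / np.log(2.0)

    n_a, n_b = la.shape[1], lb.shape[1]
    if n_a >= 2 and n_b >= 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = sps.ttest_ind(lb, la, axis=1, equal_var=False)
        # zero variance both sides: equal means -> no evidence (p=1),
        # different means -> certain change under the noise model (p=0)
        degen = (la.std(axis=1) == 0) & (lb.std(axis=1) == 0)
        p = np.where(degen & np.isclose(lfc, 0.0), 1.0, p)
        p = np.where(degen & ~np.isclose(lfc, 0.0), 0.0, p)
    else:
        p = np.full(la.shape[0], np.nan)

    records = []
    for met, fc, pv in zip(table_a.metabolite_ids, lfc, p):
        sig = bool(np.isfinite(pv) and pv < alpha and abs(fc) > lfc_min)
        records.append(DiffMetaboliteRecord(met, float(fc), float(pv), sig))
    return records


def _holm(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="holm")[1]


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def ora(
    selected: Iterable[str],
    background: Iterable[str],
    sets: Sequence[PathwaySet],
    holm_alpha: float = 0.05,
    fdr_alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of each pathway in the selection.

    ``p_hyper = P(X >= k)`` where X counts pathway members in a random draw
    of ``n`` metabolites from the ``N`` background metabolites, of which
    ``K`` belong to the pathway.  Pathways are intersected with the
    background before testing; corrections run across all tested sets.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    selected = set(selected)
    if not selected <= background:
        raise ValueError("selected metabolites must be a subset of the background")
    N, n = len(background), len(selected)

    rows = []
    for ps in sets:
        members = ps.members & background
        K = len(members)
        k = len(members & selected)
        # upper tail: survival function at k-1
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((ps.name, k, K, p))
    if not rows:
        return []
    praw = np.array([r[3] for r in rows])
    holm = _holm(praw)
    fdr = _bh(praw)
    return [
        EnrichmentRecord(
            pathway=name, k=k, K=K, n=n, N=N,
            p_hyper=p, p_holm=float(h), fdr=float(f),
            enriched=bool(h < holm_alpha and f < fdr_alpha),
        )
        for (name, k, K, p), h, f in zip(rows, holm, fdr)
    ]


def intersect_enrichment(
    results: Mapping[str, Iterable[str]],
) -> tuple[tuple[str, ...], dict[tuple[str, ...], int]]:
    """Shared enriched pathways plus the full Venn-region breakdown.

    ``results`` maps a cell-line label to the pathways enriched in it.
    Returns the sorted intersection across all lines and a dict mapping each
    nonempty label combination (exact region) to its pathway count.
    """
    if len(results) < 2:
        raise ValueError("need at least two result lists to intersect")
    sets = {label: set(v) for label, v in results.items()}
    labels = tuple(sets)
    common = set.intersection(*sets.values())

    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(set(), *(sets[l] for l in labels if l not in combo))
            regions[combo] = len(inside - outside)
    return tuple(sorted(common)), regions


def intersect_significant_metabolites(
    records: Mapping[str, Sequence[DiffMetaboliteRecord]] | Sequence[Sequence[DiffMetaboliteRecord]],
) -> tuple[str, ...]:
    """Metabolites called significant in every per-cell-line record list."""
    if isinstance(records, Mapping):
        lists = list(records.values())
    else:
        lists = list(records)
    if len(lists) < 2:
        raise ValueError("need at least two record lists to intersect")
    sig_sets = [{r.metabolite_id for r in lst if r.significant} for lst in lists]
    return tuple(sorted(set.intersection(*sig_sets)))


# ---------------------------------------------------------------------------
# GMT pathway-set format and tabular export


def read_gmt(path) -> list[PathwaySet]:
    """Read pathway sets from GMT (name <tab> description <tab> members...)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line has fewer than 3 columns: {line!r}")
            out.append(PathwaySet(name=parts[0], description=parts[1],
                                  members=frozenset(p for p in parts[2:] if p)))
    return out


def write_gmt(sets: Sequence[PathwaySet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ps in sets:
            fh.write("\t".join([ps.name, ps.description, *sorted(ps.members)]) + "\n")


def diff_records_to_frame(records: Sequence[DiffMetaboliteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metabolite": [r.metabolite_id for r in records],
            "log2_fc": [r.log2_fc for r in records],
            "p_value": [r.p_value for r in records],
            "significant": [r.significant for r in records],
        }
    ).set_index("metabolite")


def enrichment_records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in records],
            "overlap_k": [r.k for r in records],
            "set_K": [r.K for r in records],
            "selected_n": [r.n for r in records],
            "background_N": [r.N for r in records],
            "p_hyper": [r.p_hyper for r in records],
            "p_holm": [r.p_holm for r in records],
            "fdr": [r.fdr for r in records],
            "enriched": [r.enriched for r in records],
        }
    ).set_index("pathway")
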