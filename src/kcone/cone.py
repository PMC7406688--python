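"""Mass-action k-cone analysis and differential enzyme-activity inference.

At steady state a mass-action network satisfies ``S · diag(M(x)) · k = 0``
with ``k >= 0``, where S is the stoichiometric matrix, x the metabolome
snapshot, ``M_i(x)`` the product of substrate concentrations of step i
raised to their stoichiometric multiplicities, and k the vector of rate
constants.  The *k-cone* is the polyhedral cone of all rate-constant
vectors consistent with the observed metabolome; its extreme rays are the
elementwise rescaling of the flux cone's rays by 1/M.

Comparing the cones of two conditions that share the same flux distribution
gives the per-step activity ratio ``k_B / k_A = M_A / M_B``: a reaction
whose substrate pool shrank while carrying the same flux must have become
more active.  :func:`differential_activity` turns replicate concentration
tables into per-step log2 activity fold changes with a one-sample test and
FDR control.

Extreme rays are enumerated with an exact-rational double description
method, so residuals are exactly zero in rational mode.  An independent
brute-force support-enumeration oracle (:func:`enumerate_rays_bruteforce`)
is provided for verification on small networks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .network import MetabolicNetwork, StoichiometricMatrix
from .stats import ConcentrationTable

__all__ = [
    "MassActionState",
    "KConeBasis",
    "ActivityChangeRecord",
    "mass_action_terms",
    "kcone_basis",
    "transform_cone",
    "kcone_residual",
    "differential_activity",
    "annotate_with_expression",
    "enumerate_rays_bruteforce",
    "activity_records_to_frame",
]


# ---------------------------------------------------------------------------
# Mass-action terms


@dataclass(frozen=True)
class MassActionState:
    """Per-step mass-action terms M(x) for one concentration snapshot."""

    step_ids: tuple[str, ...]
    M: tuple[Fraction, ...]  # exact positive terms, one per step
    convention: str = "substrate"

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.M):
            raise ValueError("mass-action terms must be strictly positive")

    def to_float(self) -> np.ndarray:
        return np.array([float(m) for m in self.M])


def mass_action_terms(
    network: MetabolicNetwork,
    x: Mapping[str, float | Fraction],
    unmeasured: str = "strict",
    convention: str = "substrate",
) -> MassActionState:
    """Compute M_i(x) for every step of a reversibility-split network.

    ``convention="substrate"`` (default, mass-action kinetics):
    ``M_i = prod over internal substrates j of x_j ** |S_ji|``; a step whose
    substrates are all boundary species has ``M_i = 1`` (constant influx).
    ``convention="literal"`` uses signed exponents over *all* participants,
    ``M_i = prod_j x_j ** S_ji`` (products contribute inverse powers) — a
    sensitivity-analysis variant, not the default kinetics.

    ``unmeasured``: "strict" raises on an internal metabolite missing from
    ``x``; "one" substitutes the neutral concentration 1.
    """
    if not network.is_split():
        raise ValueError("network must be reversibility-split")
    if convention not in ("substrate", "literal"):
        raise ValueError(f"unknown convention {convention!r}")
    internal = set(network.internal_ids)

    conc: dict[str, Fraction] = {}
    for m in internal:
        if m in x:
            v = x[m]
            if not (isinstance(v, Fraction) and v > 0) and not (float(v) > 0):
                raise ValueError(f"non-positive concentration for {m!r}")
            conc[m] = v if isinstance(v, Fraction) else Fraction(str(float(v)))
        elif unmeasured == "one":
            conc[m] = Fraction(1)
        else:
            raise ValueError(f"no concentration for internal metabolite {m!r}")

    def _pow(base: Fraction, e: Fraction) -> Fraction:
        if e.denominator == 1:
            return base ** e.numerator  # exact for integer multiplicities
        return Fraction(float(base) ** float(e))  # fractional: float-backed

    terms = []
    for r in network.reactions:
        t = Fraction(1)
        for met, c in r.stoich.items():
            if met not in internal:
                continue
            if convention == "substrate":
                if c < 0:
                    t *= _pow(conc[met], -c)  # exponent |S_ji|
            else:
                t *= _pow(conc[met], c)  # literal signed exponents
        terms.append(t)
    return MassActionState(step_ids=network.reaction_ids, M=tuple(terms), convention=convention)


# ---------------------------------------------------------------------------
# Exact double description on {k >= 0 : A k = 0}


def _zero_set(ray: Sequence[Fraction]) -> frozenset[int]:
    return frozenset(i for i, v in enumerate(ray) if v == 0)


def _canonical(ray: Sequence[Fraction]) -> tuple[Fraction, ...]:
    mx = max(ray)
    return tuple(v / mx for v in ray)


def _double_description(A: np.ndarray, d: int) -> list[tuple[Fraction, ...]]:
    """Extreme rays of {k in R^d : k >= 0, A k = 0}, exact Fractions.

    Starts from the nonnegative orthant (rays = unit vectors) and cuts with
    each equality in turn, combining adjacent positive/negative rays.
    Adjacency uses the combinatorial test on coordinate zero-sets.
    """
    rays: list[tuple[Fraction, ...]] = [
        tuple(Fraction(int(i == j)) for i in range(d)) for j in range(d)
    ]
    for row in A:
        vals = [sum(a * r for a, r in zip(row, ray)) for ray in rays]
        zero = [r for r, v in zip(rays, vals) if v == 0]
        pos = [(r, v) for r, v in zip(rays, vals) if v > 0]
        neg = [(r, v) for r, v in zip(rays, vals) if v < 0]
        new: list[tuple[Fraction, ...]] = list(zero)
        zsets = [_zero_set(r) for r in rays]
        for (rp, vp), (rn, vn) in itertools.product(pos, neg):
            zp, zn = _zero_set(rp), _zero_set(rn)
            inter = zp & zn
            adjacent = not any(
                z >= inter and r is not rp and r is not rn
                for r, z in zip(rays, zsets)
            )
            if not adjacent:
                continue
            combo = tuple(vp * b - vn * a for a, b in zip(rp, rn))
            if any(v != 0 for v in combo):
                new.append(_canonical(combo))
        # dedupe canonically
        seen: dict[tuple, tuple] = {}
        for r in new:
            seen.setdefault(_canonical(r), _canonical(r))
        rays = list(seen.values())
        if not rays:
            return []
    return rays


@dataclass(frozen=True)
class KConeBasis:
    """Extreme rays of the k-cone, one column per ray over reaction steps."""

    step_ids: tuple[str, ...]
    rays: tuple[tuple[Fraction, ...], ...]  # each normalized to max entry 1
    condition: str = ""
    residual_tol: float = 1e-9

    @property
    def n_rays(self) -> int:
        return len(self.rays)

    def to_float(self) -> np.ndarray:
        """Steps x rays float matrix (empty basis -> shape (n_steps, 0))."""
        if not self.rays:
            return np.zeros((len(self.step_ids), 0))
        return np.array([[float(v) for v in r] for r in self.rays]).T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.to_float(), index=self.step_ids,
            columns=[f"ray{i + 1}" for i in range(self.n_rays)],
        )


def _sort_rays(rays: Iterable[tuple[Fraction, ...]]) -> tuple[tuple[Fraction, ...], ...]:
    # deterministic: by support pattern, then entry values
    return tuple(sorted(rays, key=lambda r: (tuple(v == 0 for v in r), tuple(float(v) for v in r))))


def kcone_basis(
    S: StoichiometricMatrix,
    M: MassActionState,
    condition: str = "",
    residual_tol: float = 1e-9,
) -> KConeBasis:
    """Enumerate the extreme rays of {k >= 0 : S·diag(M)·k = 0}.

    Computation is exact (rational), so every returned ray satisfies the
    steady-state balance with zero residual.  A cone containing only the
    origin yields an empty basis (not an error).
    """
    if tuple(M.step_ids) != tuple(S.col_ids):
        raise ValueError("mass-action terms do not match the matrix columns")
    n_rows, n_cols = S.shape
    A = np.empty((n_rows, n_cols), dtype=object)
    for i in range(n_rows):
        for j in range(n_cols):
            A[i, j] = Fraction(S.entries[i, j]) * M.M[j]
    rays = _double_description(A, n_cols)
    return KConeBasis(
        step_ids=tuple(S.col_ids),
        rays=_sort_rays(_canonical(r) for r in rays),
        condition=condition,
        residual_tol=residual_tol,
    )


def kcone_residual(S: StoichiometricMatrix, M: MassActionState, k: Sequence) -> float | Fraction:
    """max_i |(S · diag(M) · k)_i|; exact when k is given in Fractions."""
    if len(k) != S.shape[1]:
        raise ValueError("candidate vector length does not match matrix columns")
    exact = all(isinstance(v, (Fraction, int)) for v in k)
    worst: Fraction | float = Fraction(0) if exact else 0.0
    for i in range(S.shape[0]):
        acc = Fraction(0) if exact else 0.0
        for j in range(S.shape[1]):
            sij = S.entries[i, j]
            if sij == 0:
                continue
            term = sij * M.M[j] * k[j] if exact else float(sij) * float(M.M[j]) * float(k[j])
            acc += term
        worst = max(worst, abs(acc))
    return worst


def transform_cone(basis_a: KConeBasis, M_a: MassActionState, M_b: MassActionState) -> KConeBasis:
    """Map condition-A rays onto condition B via ``k_b = (M_a / M_b) ⊙ k_a``.

    Both cones are rescalings of the same flux cone, so this elementwise
    transform carries extreme rays to extreme rays; re-normalization keeps
    the max-entry-1 convention.
    """
    if tuple(M_a.step_ids) != tuple(M_b.step_ids) or tuple(M_a.step_ids) != tuple(basis_a.step_ids):
        raise ValueError("term vectors and basis must share step ordering")
    ratio = [a / b for a, b in zip(M_a.M, M_b.M)]
    rays = [_canonical(tuple(r * v for r, v in zip(ratio, ray))) for ray in basis_a.rays]
    return KConeBasis(
        step_ids=basis_a.step_ids,
        rays=_sort_rays(rays),
        condition=f"{basis_a.condition}:transformed" if basis_a.condition else "transformed",
        residual_tol=basis_a.residual_tol,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle (independent check, small networks only)


def enumerate_rays_bruteforce(
    S: StoichiometricMatrix, M: MassActionState, max_steps: int = 12
) -> list[tuple[Fraction, ...]]:
    """Enumerate extreme rays by exhaustive support enumeration.

    For every subset J of steps, an extreme ray supported exactly on J
    exists iff the restricted system S·diag(M) on columns J has a
    one-dimensional null space whose generator can be taken strictly
    positive.  Exponential in the number of steps; intended as an oracle on
    toy systems, independent of the double-description path.
    """
    n_cols = S.shape[1]
    if n_cols > max_steps:
        raise ValueError("bruteforce oracle limited to small networks")
    def _rat(f: Fraction) -> sympy.Rational:
        return sympy.Rational(int(f.numerator), int(f.denominator))

    A = sympy.Matrix(
        [[_rat(Fraction(S.entries[i, j])) * _rat(Fraction(M.M[j])) for j in range(n_cols)]
         for i in range(S.shape[0])]
    )
    found: dict[tuple, tuple[Fraction, ...]] = {}
    supports: list[frozenset[int]] = []
    for size in range(1, n_cols + 1):
        for J in itertools.combinations(range(n_cols), size):
            Jset = frozenset(J)
            if any(s < Jset for s in supports):
                continue  # a smaller support already gives a ray inside this face
            sub = A[:, list(J)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            v = null[0]
            vals = [sympy.nsimplify(v[i]) for i in range(size)]
            if all(val > 0 for val in vals):
                pass
            elif all(val < 0 for val in vals):
                vals = [-val for val in vals]
            else:
                continue
            ray = [Fraction(0)] * n_cols
            for idx, val in zip(J, vals):
                ray[idx] = Fraction(int(val.p), int(val.q)) if val.is_Rational else Fraction(float(val))
            found[tuple(_canonical(ray))] = tuple(_canonical(ray))
            supports.append(Jset)
    return list(_sort_rays(found.values()))


# ---------------------------------------------------------------------------
# Differential activity between two conditions


@dataclass(frozen=True)
class ActivityChangeRecord:
    step_id: str
    mean_log2_fc: float  # mean log2(k_B / k_A) over replicate pairs
    sd: float
    p_value: float  # NaN when undefined (single pair)
    q_value: float
    direction: str  # up | down | unchanged
    constant_term: bool = False  # M is 1 by construction (boundary-only substrates)
    uses_unmeasured: bool = False
    genes: tuple[str, ...] = ()
    gene_direction: str = ""
    concordant: str = ""


def _pairings(n_a: int, n_b: int, policy: str) -> list[tuple[int, int]]:
    if policy == "cross":
        return [(i, j) for i in range(n_a) for j in range(n_b)]
    if policy == "index":
        if n_a != n_b:
            raise ValueError("index pairing requires equal replicate counts")
        return [(i, i) for i in range(n_a)]
    raise ValueError(f"unknown pairing policy {policy!r}")


def differential_activity(
    network: MetabolicNetwork,
    table_a: ConcentrationTable,
    table_b: ConcentrationTable,
    alpha: float = 0.05,
    pairing: str = "cross",
    unmeasured: str = "one",
    convention: str = "substrate",
    correction: str = "bh",
    lfc_fallback: float = 1.0,
) -> list[ActivityChangeRecord]:
    """Per-step inferred enzyme-activity change from A to B.

    For each replicate pair (p, q) the flux-invariance relation
    ``v = M_A·k_A = M_B·k_B`` gives the log activity ratio
    ``log2(k_B/k_A) = log2(M_A(x_p) / M_B(x_q))`` per step.  The sample of
    ratios is tested against 0 with a one-sample t-test whose degrees of
    freedom are ``min(n_A, n_B) - 1`` — cross pairs reuse replicates, so the
    effective sample size is the smaller replicate count, not the number of
    pairs.  Benjamini-Hochberg (or Holm) correction runs across steps;
    "up" means higher activity in condition B.

    Steps whose M is constant by construction (all substrates boundary) are
    reported unchanged with fold change 0.  With a single replicate pair the
    p-value is undefined and direction falls back to the ``|log2 fc| >
    lfc_fallback`` rule.
    """
    if not network.is_split():
        raise ValueError("network must be reversibility-split")
    pairs = _pairings(table_a.n_replicates, table_b.n_replicates, pairing)
    if not pairs:
        raise ValueError("no valid replicate pairs")
    internal = set(network.internal_ids)
    measured = set(table_a.metabolite_ids) & set(table_b.metabolite_ids)
    uses_unmeasured = {
        r.id: any(m in internal and m not in measured for m in r.substrates)
        for r in network.reactions
    }
    constant = {
        r.id: not any(m in internal for m in (r.substrates if convention == "substrate" else r.stoich))
        for r in network.reactions
    }

    def terms(table: ConcentrationTable, rep: int) -> np.ndarray:
        x = {m: v for m, v in table.replicate(rep).items() if m in internal}
        return mass_action_terms(network, x, unmeasured=unmeasured, convention=convention).to_float()

    Ma = [terms(table_a, i) for i in range(table_a.n_replicates)]
    Mb = [terms(table_b, j) for j in range(table_b.n_replicates)]
    ratios = np.array([np.log2(Ma[i]) - np.log2(Mb[j]) for i, j in pairs])  # pairs x steps

    mean = ratios.mean(axis=0)
    sd = ratios.std(axis=0, ddof=1) if len(pairs) > 1 else np.zeros(ratios.shape[1])
    n_eff = min(table_a.n_replicates, table_b.n_replicates)
    df = n_eff - 1

    step_ids = network.reaction_ids
    p = np.full(len(step_ids), np.nan)
    if df >= 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            se = sd / np.sqrt(n_eff)
            t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), np.inf * np.sign(mean))
        p = 2.0 * sps.t.sf(np.abs(t), df)
        p = np.where((sd == 0) & (mean == 0), 1.0, p)
        p = np.where((sd == 0) & (mean != 0), 0.0, p)
    for idx, sid in enumerate(step_ids):
        if constant[sid]:
            mean[idx], sd[idx], p[idx] = 0.0, 0.0, np.nan

    testable = [i for i, sid in enumerate(step_ids) if not constant[sid] and np.isfinite(p[i])]
    q = np.full(len(step_ids), np.nan)
    if testable:
        method = {"bh": "fdr_bh", "holm": "holm"}[correction]
        q[testable] = multipletests(p[testable], method=method)[1]

    records = []
    gene_map = {r.id: r.genes for r in network.reactions}
    for i, sid in enumerate(step_ids):
        if constant[sid]:
            direction = "unchanged"
        elif np.isfinite(q[i]):
            if q[i] < alpha:
                direction = "up" if mean[i] > 0 else "down"
            else:
                direction = "unchanged"
        else:  # p undefined: single-pair fallback on effect size
            if abs(mean[i]) > lfc_fallback:
                direction = "up" if mean[i] > 0 else "down"
            else:
                direction = "unchanged"
        records.append(
            ActivityChangeRecord(
                step_id=sid,
                mean_log2_fc=float(mean[i]),
                sd=float(sd[i]),
                p_value=float(p[i]),
                q_value=float(q[i]),
                direction=direction,
                constant_term=constant[sid],
                uses_unmeasured=uses_unmeasured[sid],
                genes=gene_map[sid],
            )
        )
    return records


def annotate_with_expression(
    records: Sequence[ActivityChangeRecord],
    gene_de: pd.DataFrame,
    alpha: float = 0.05,
) -> list[ActivityChangeRecord]:
    """Overlay a precomputed gene-level differential-expression table.

    ``gene_de`` needs columns ``gene``, ``log2_fc`` and one of ``q_value`` /
    ``p_value``.  Each record gains the direction of its significant genes
    and a concordance call: "concordant" / "discordant" when enzymatic and
    transcript directions agree/disagree, "ambiguous" when mapped genes
    disagree among themselves, "" when nothing maps.
    """
    de = gene_de.set_index("gene") if "gene" in gene_de.columns else gene_de
    pcol = "q_value" if "q_value" in de.columns else "p_value"
    out = []
    for rec in records:
        dirs = set()
        for g in rec.genes:
            if g in de.index and de.loc[g, pcol] < alpha:
                dirs.add("up" if de.loc[g, "log2_fc"] > 0 else "down")
        if not dirs:
            annotated = ("", "")
        elif len(dirs) > 1:
            annotated = ("mixed", "ambiguous")
        else:
            gdir = dirs.pop()
            if rec.direction == "unchanged":
                concord = "discordant"
            else:
                concord = "concordant" if gdir == rec.direction else "discordant"
            annotated = (gdir, concord)
        out.append(
            ActivityChangeRecord(
                **{**rec.__dict__, "gene_direction": annotated[0], "concordant": annotated[1]}
            )
        )
    return out


def activity_records_to_frame(records: Sequence[ActivityChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "step": [r.step_id for r in records],
            "mean_log2_fc": [r.mean_log2_fc for r in records],
            "sd": [r.sd for r in records],
            "p_value": [r.p_value for r in records],
            "q_value": [r.q_value for r in records],
            "direction": [r.direction for r in records],
            "constant_term": [r.constant_term for r in records],
            "uses_unmeasured": [r.uses_unmeasured for r in records],
            "genes": [",".join(r.genes) for r in records],
            "gene_direction": [r.gene_direction for r in records],
            "concordant": [r.concordant for r in records],
        }
    ).set_index("step")
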