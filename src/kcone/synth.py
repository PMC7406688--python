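"""Ground-truthed synthetic metabolome experiments.

The generator realizes exactly the assumptions the k-cone analysis makes:
a mass-action network driven to steady state by constant boundary influxes,
observed in two conditions that differ by known enzyme-activity fold
changes, with multiplicative lognormal replicate noise on the measured
concentrations.  Because the truth (which steps changed and by how much) is
known, every downstream stage — differential metabolites, enrichment,
activity inference — can be scored without external data.

Influxes are zero-order (constant rate), so a perturbation of an interior
step leaves the steady-state flux unchanged; in that flux-invariant regime
the activity estimator ``log2(M_A/M_B)`` is exact at zero noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import MetabolicNetwork, parse_reaction_file, split_reversible, stoichiometric_matrix
from .stats import ConcentrationTable
from .cone import mass_action_terms

__all__ = [
    "KineticModel",
    "SyntheticExperiment",
    "toy_network",
    "simulate_steady_state",
    "perturb_model",
    "sample_replicates",
    "generate_experiment",
    "parallel_chains_network",
    "three_cell_line_scenario",
]


_CHAIN = """
# linear pathway: uptake, conversion, secretion
R1: X_ext -> A
R2: A -> B
R3: B -> Y_ext
"""

_BRANCH = """
# one branchpoint, two secretion routes
R1: X_ext -> A
R2: A -> B
R3: A -> C
R4: B -> Y_ext
R5: C -> Z_ext
"""

# toy glutathione motif: synthesis (GCL, GSS), peroxidase/reductase redox
# cycle (GPX, GSR) and degradation (GGT, APN), with amino-acid uptake
_GSH_MOTIF = """
GLU_IN: glu_ext -> glu
CYS_IN: cys_ext -> cys
GLY_IN: gly_ext -> gly
GCL: glu + cys -> glucys genes=GCLC,GCLM pathways=glutathione
GSS: glucys + gly -> gsh genes=GSS pathways=glutathione
GPX: 2 gsh -> gssg genes=GPX1,GPX2 pathways=glutathione
GSR: gssg -> 2 gsh genes=GSR pathways=glutathione
GGT: gsh -> cysgly + glu_ext genes=GGT1 pathways=glutathione
APN: cysgly -> cysgly_ext genes=ANPEP pathways=glutathione
"""

_TOY_RATES = {
    "chain": {"R1": 1.0, "R2": 2.0, "R3": 4.0},
    "branch": {"R1": 1.0, "R2": 1.0, "R3": 1.0, "R4": 2.0, "R5": 2.0},
    "gsh_motif": {
        "GLU_IN": 1.0, "CYS_IN": 1.0, "GLY_IN": 1.0,
        "GCL": 1.0, "GSS": 1.0, "GPX": 0.5, "GSR": 1.0, "GGT": 1.0, "APN": 2.0,
    },
}
_TOY_TEXT = {"chain": _CHAIN, "branch": _BRANCH, "gsh_motif": _GSH_MOTIF}


@dataclass(frozen=True)
class KineticModel:
    """A reversibility-split network plus ground-truth rate constants.

    Steps whose substrates are all boundary species act as constant
    influxes (their mass-action term is 1, so the rate is just k).
    """

    network: MetabolicNetwork
    k_true: Mapping[str, float]
    non_flux_invariant: bool = False

    def __post_init__(self) -> None:
        if not self.network.is_split():
            raise ValueError("model network must be reversibility-split")
        missing = set(self.network.reaction_ids) - set(self.k_true)
        if missing:
            raise ValueError(f"rate constants missing for steps {sorted(missing)}")
        if any(v <= 0 for v in self.k_true.values()):
            raise ValueError("rate constants must be positive")

    @property
    def influx_steps(self) -> tuple[str, ...]:
        internal = set(self.network.internal_ids)
        return tuple(
            r.id for r in self.network.reactions
            if not any(m in internal for m in r.substrates)
        )

    def k_vector(self) -> np.ndarray:
        return np.array([self.k_true[s] for s in self.network.reaction_ids])


def toy_network(name: str) -> KineticModel:
    """Hand-curated small models: ``chain``, ``branch`` or ``gsh_motif``."""
    if name not in _TOY_TEXT:
        raise ValueError(f"unknown toy network {name!r}; options: {sorted(_TOY_TEXT)}")
    net = split_reversible(parse_reaction_file(_TOY_TEXT[name]))
    return KineticModel(network=net, k_true=dict(_TOY_RATES[name]))


def simulate_steady_state(
    model: KineticModel,
    tol: float = 1e-10,
    t_max: float = 1e7,
    x0: Mapping[str, float] | None = None,
    overflow: float = 1e9,
) -> dict[str, float]:
    """Integrate dx/dt = S·v(x), v_i = k_i·M_i(x), until dx/dt vanishes.

    Starts from x = 1 (or ``x0``), integrates with a stiff-capable method in
    doubling windows, and stops when ``max|dx/dt| < tol``.  Raises if the
    system has not settled by ``t_max`` or any concentration exceeds the
    overflow guard.
    """
    net = model.network
    S = stoichiometric_matrix(net).to_float()
    internal = list(net.internal_ids)
    k = model.k_vector()

    # precompute substrate (metabolite index, multiplicity) lists per step
    idx = {m: i for i, m in enumerate(internal)}
    subs: list[list[tuple[int, float]]] = []
    for r in net.reactions:
        subs.append([(idx[m], float(-c)) for m, c in r.stoich.items() if c < 0 and m in idx])

    def rates(x: np.ndarray) -> np.ndarray:
        v = k.copy()
        for j, lst in enumerate(subs):
            for i, e in lst:
                v[j] *= x[i] ** e
        return v

    def rhs(_t, x):
        return S @ rates(np.maximum(x, 1e-300))

    x = np.array([float((x0 or {}).get(m, 1.0)) for m in internal])
    t, window = 0.0, 10.0
    while t < t_max:
        sol = solve_ivp(rhs, (0.0, window), x, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        x = sol.y[:, -1]
        t += window
        window *= 2.0
        if np.any(x > overflow):
            raise RuntimeError("divergence: concentration exceeded overflow guard")
        resid = np.max(np.abs(rhs(0.0, x)))
        if resid < tol:
            if np.any(x <= 0):
                raise RuntimeError("steady state reached non-positive concentrations")
            return {m: float(v) for m, v in zip(internal, x)}
    raise RuntimeError(f"no steady state by t_max={t_max}; final residual {resid:.3e}")


def perturb_model(model: KineticModel, changes: Mapping[str, float]) -> KineticModel:
    """Multiply selected rate constants by fold factors (condition B truth).

    Perturbing an influx step changes the steady-state flux itself; the
    returned model is then flagged ``non_flux_invariant`` because the
    constant-flux assumption behind the activity estimator no longer holds.
    """
    unknown = set(changes) - set(model.network.reaction_ids)
    if unknown:
        raise ValueError(f"unknown step ids {sorted(unknown)}")
    if any(f <= 0 for f in changes.values()):
        raise ValueError("fold changes must be positive")
    k = dict(model.k_true)
    for s, f in changes.items():
        k[s] = k[s] * f
    touched_influx = bool(set(changes) & set(model.influx_steps))
    return replace(model, k_true=k, non_flux_invariant=model.non_flux_invariant or touched_influx)


def sample_replicates(
    x: Mapping[str, float],
    n: int,
    cv: float,
    seed: int,
    condition: str = "sample",
) -> ConcentrationTable:
    """Draw ``n`` lognormal replicates with median x and coefficient of
    variation ``cv`` (log-sd = sqrt(log(1 + cv^2))); seed-deterministic."""
    if n < 1:
        raise ValueError("need at least one replicate")
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    rng = np.random.default_rng(seed)
    mets = list(x)
    base = np.array([x[m] for m in mets])[:, None]
    sigma = np.sqrt(np.log1p(cv**2))
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=(len(mets), n)) if cv > 0 else np.ones((len(mets), n))
    df = pd.DataFrame(base * noise, index=mets, columns=[f"rep{i + 1}" for i in range(n)])
    return ConcentrationTable(condition=condition, values=df)


@dataclass(frozen=True)
class SyntheticExperiment:
    """Paired condition tables plus the generating ground truth."""

    table_a: ConcentrationTable
    table_b: ConcentrationTable
    truth: Mapping[str, float]  # step id -> true log2 fold change of k
    model_a: KineticModel
    model_b: KineticModel
    seed: int
    noise_cv: float

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": list(self.truth), "true_log2_fc": list(self.truth.values())}
        ).set_index("step")

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "noise_cv": self.noise_cv,
            "n_replicates": [self.table_a.n_replicates, self.table_b.n_replicates],
            "perturbed_steps": sorted(s for s, f in self.truth.items() if f != 0.0),
            "non_flux_invariant": self.model_b.non_flux_invariant,
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table_a.to_tsv(out / "condition_a.tsv")
        self.table_b.to_tsv(out / "condition_b.tsv")
        self.truth_frame().to_csv(out / "truth.tsv", sep="\t")
        (out / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))


def generate_experiment(
    model: KineticModel | str,
    perturbations: Mapping[str, float] | None = None,
    n: int = 3,
    cv: float = 0.1,
    seed: int = 0,
    labels: tuple[str, str] = ("pre", "post"),
) -> SyntheticExperiment:
    """Simulate both conditions to steady state and sample noisy replicates.

    ``model`` may be a toy-network name.  ``perturbations`` maps step ids to
    positive fold factors applied to condition B's rate constants; the
    recorded truth is their log2.  A pure function of its arguments: the
    same config and seed always produce the same tables.
    """
    if isinstance(model, str):
        model = toy_network(model)
    perturbations = dict(perturbations or {})
    model_b = perturb_model(model, perturbations)

    x_a = simulate_steady_state(model)
    x_b = simulate_steady_state(model_b)
    table_a = sample_replicates(x_a, n, cv, seed=seed * 2 + 1, condition=labels[0])
    table_b = sample_replicates(x_b, n, cv, seed=seed * 2 + 2, condition=labels[1])
    truth = {
        s: float(np.log2(perturbations.get(s, 1.0))) for s in model.network.reaction_ids
    }
    return SyntheticExperiment(
        table_a=table_a, table_b=table_b, truth=truth,
        model_a=model, model_b=model_b, seed=seed, noise_cv=cv,
    )


# ---------------------------------------------------------------------------
# Multi-cell-line scenario built from independent parallel pathways


def parallel_chains_network(n_chains: int = 14) -> KineticModel:
    """``n_chains`` independent uptake -> metabolite -> secretion chains.

    Each chain's steady state is x_i = influx_i / k_out_i, so perturbing one
    secretion step moves exactly one metabolite — a designable ground truth
    for filter/intersection logic.
    """
    lines = []
    k = {}
    for i in range(1, n_chains + 1):
        m = f"M{i:02d}"
        lines.append(f"IN_{m}: {m}_ext -> {m}")
        lines.append(f"OUT_{m}: {m} -> {m}_sink_ext")
        k[f"IN_{m}"] = 1.0
        k[f"OUT_{m}"] = 1.0
    net = split_reversible(parse_reaction_file("\n".join(lines)))
    return KineticModel(network=net, k_true=k)


def three_cell_line_scenario(
    seed: int = 0,
    n: int = 3,
    cv: float = 0.1,
    fold: float = 4.0,
    n_chains: int = 14,
    n_shared: int = 6,
) -> dict[str, SyntheticExperiment]:
    """Three synthetic cell lines sharing a core metabolic response.

    All lines perturb the secretion steps of the first ``n_shared`` chains
    (the shared EMT-like core); each line additionally perturbs two
    line-specific chains.  The shared truly-altered metabolites are
    ``M01..M{n_shared}``; the remaining chains are nulls.
    """
    model = parallel_chains_network(n_chains)
    specific = {
        "line1": (n_shared + 1, n_shared + 2),
        "line2": (n_shared + 3, n_shared + 4),
        "line3": (n_shared + 5, n_shared + 6),
    }
    if n_shared + 6 > n_chains:
        raise ValueError("not enough chains for shared + line-specific perturbations")
    out = {}
    for li, (line, extras) in enumerate(specific.items()):
        perts = {f"OUT_M{i:02d}": fold for i in range(1, n_shared + 1)}
        perts.update({f"OUT_M{i:02d}": fold for i in extras})
        out[line] = generate_experiment(
            model, perts, n=n, cv=cv, seed=seed * 1000 + li, labels=("pre", "post")
        )
    return out
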