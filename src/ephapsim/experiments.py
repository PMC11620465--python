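"""Condition grids, per-seed complexity aggregation and rank-sum comparisons.

A *condition* is a full simulation configuration minus the seed; running it
means simulating ``n_seeds`` realisations (seeds ``seed_base + i``),
extracting the LFP of each, computing its multiscale-entropy curve and the
integrated complexity K.  Ephaptic-on/off members of a comparison pair share
seeds, so their synaptic topologies, neuron parameters and initial
conditions are identical and the regime is the only difference.

Regime contrasts are tested with the two-sided Wilcoxon rank-sum
(Mann-Whitney) test, with the usual star labels (* p<0.05, ** p<0.01,
*** p<0.001, otherwise ns).  :func:`sweep` runs a list of paired conditions
into a long-format table plus a comparison table, with a run ledger keyed on
(config hash, seed) so interrupted grids resume instead of recomputing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .complexity import DEFAULT_TAUS, complexity_K, mse_curve
from .simulator import SimulationConfig, run_network
from .topology import DEFAULT_EPHAPTIC_FACTOR

__all__ = ["ConditionSpec", "ConditionResult", "ComparisonResult",
           "run_condition", "wilcoxon_compare", "significance_label", "sweep",
           "grid_rewiring", "grid_network_size", "grid_synaptic_intensity",
           "grid_neighborhood", "load_grid"]


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: simulation + entropy parameters, n_seeds."""

    n_neurons: int = 100
    nb: int = 4
    rp: float = 0.1
    omega: float = 5.0
    ephaptic_enabled: bool = True
    ephaptic_factor: float = DEFAULT_EPHAPTIC_FACTOR
    inhib_fraction: float = 0.0
    dt: float = 1e-3
    duration: float = 60.0
    transient: float = 10.0
    m: int = 2
    r_frac: float = 0.15
    tau_min: int = 2
    tau_max: int = 100
    n_seeds: int = 20
    seed_base: int = 0

    def sim_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            n_neurons=self.n_neurons, nb=self.nb, rp=self.rp, omega=self.omega,
            ephaptic_enabled=self.ephaptic_enabled,
            ephaptic_factor=self.ephaptic_factor,
            inhib_fraction=self.inhib_fraction, dt=self.dt,
            duration=self.duration, transient=self.transient, seed=seed)

    @property
    def seeds(self) -> list[int]:
        return [self.seed_base + i for i in range(self.n_seeds)]

    @property
    def taus(self) -> np.ndarray:
        return np.arange(self.tau_min, self.tau_max + 1)

    def config_hash(self) -> str:
        """Stable hash of the physics/analysis parameters (seeds excluded)."""
        d = asdict(self)
        d.pop("n_seeds")
        d.pop("seed_base")
        blob = json.dumps(d, sort_keys=True)
        return hashlib.md5(blob.encode()).hexdigest()[:12]

    def paired(self) -> tuple["ConditionSpec", "ConditionSpec"]:
        """(ephaptic-on, ephaptic-off) pair sharing every other field."""
        return (replace(self, ephaptic_enabled=True),
                replace(self, ephaptic_enabled=False))


@dataclass
class ConditionResult:
    """K per seed and the mean MSE curve of one condition."""

    spec: ConditionSpec
    seeds: list[int]
    k_values: np.ndarray
    mse_curves: np.ndarray = field(repr=False)  # (n_seeds, n_taus)

    @property
    def mse_mean(self) -> np.ndarray:
        return np.nanmean(self.mse_curves, axis=0)

    @property
    def k_mean(self) -> float:
        return float(self.k_values.mean())


@dataclass
class ComparisonResult:
    """Two-sided rank-sum test between two K samples."""

    statistic: float
    p_value: float
    stars: str
    n_x: int
    n_y: int


def _k_for_seed(spec: ConditionSpec, seed: int) -> tuple[float, np.ndarray]:
    lfp = run_network(spec.sim_config(seed))
    curve = mse_curve(lfp.x, taus=spec.taus, m=spec.m, r_frac=spec.r_frac)
    return complexity_K(curve).K, curve.se


def run_condition(spec: ConditionSpec) -> ConditionResult:
    """Simulate and score every seed of a condition.

    A failure in any seed aborts the condition with the offending seed named
    in the exception chain.
    """
    ks = np.empty(spec.n_seeds)
    curves = np.empty((spec.n_seeds, len(spec.taus)))
    for i, seed in enumerate(spec.seeds):
        try:
            ks[i], curves[i] = _k_for_seed(spec, seed)
        except Exception as exc:  # pragma: no cover - context wrapper
            raise RuntimeError(f"condition {spec.config_hash()} failed at seed {seed}") from exc
    return ConditionResult(spec=spec, seeds=spec.seeds, k_values=ks, mse_curves=curves)


def significance_label(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def wilcoxon_compare(x, y) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test with star labelling.

    Uses the exact null distribution when the combined sample is small
    (n <= 20) and tie-free, otherwise the normal approximation with tie
    correction.  Two identical samples give p = 1 ("ns").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return ComparisonResult(statistic=x.size * y.size / 2.0, p_value=1.0,
                                stars="ns", n_x=x.size, n_y=y.size)
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (not has_ties and combined.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=False)
    p = float(res.pvalue)
    return ComparisonResult(statistic=float(res.statistic), p_value=p,
                            stars=significance_label(p), n_x=x.size, n_y=y.size)


# ---------------------------------------------------------------------------
# sweeps

_LEDGER_COLUMNS = ["config_hash", "seed", "n_neurons", "nb", "rp", "omega",
                   "ephaptic_enabled", "ephaptic_factor", "inhib_fraction",
                   "dt", "duration", "transient", "m", "r_frac",
                   "tau_min", "tau_max", "K"]


def _load_ledger(path: Path) -> pd.DataFrame:
    if path.exists():
        return pd.read_csv(path)
    return pd.DataFrame(columns=_LEDGER_COLUMNS)


def sweep(pairs, out_dir=None, verbose: bool = False):
    """Run a list of (on, off) condition pairs into summary tables.

    Returns ``(results, comparisons)``: a long-format DataFrame with one row
    per (condition, seed) and a DataFrame with one rank-sum comparison per
    pair.  With ``out_dir`` the tables are written as ``results.csv`` and
    ``comparisons.csv``; ``results.csv`` doubles as the run ledger — cells
    already present (matched on config hash and seed) are reused, so a
    partially completed grid resumes instead of recomputing.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    ledger_path = out_dir / "results.csv" if out_dir else None
    ledger = _load_ledger(ledger_path) if ledger_path else pd.DataFrame(columns=_LEDGER_COLUMNS)
    done = set(zip(ledger["config_hash"], ledger["seed"].astype(int))) if len(ledger) else set()

    rows = []
    for pair in pairs:
        for spec in pair:
            h = spec.config_hash()
            for seed in spec.seeds:
                if (h, seed) in done:
                    continue
                if verbose:
                    print(f"[sweep] {h} seed={seed} "
                          f"(N={spec.n_neurons} nb={spec.nb} rp={spec.rp} "
                          f"omega={spec.omega} eph={spec.ephaptic_enabled})")
                k, _ = _k_for_seed(spec, seed)
                d = asdict(spec)
                d.pop("n_seeds")
                d.pop("seed_base")
                rows.append({"config_hash": h, "seed": seed, **d, "K": k})
                done.add((h, seed))
    if rows:
        new = pd.DataFrame(rows)
        ledger = new if ledger.empty else pd.concat([ledger, new], ignore_index=True)
    if ledger_path:
        out_dir.mkdir(parents=True, exist_ok=True)
        ledger.to_csv(ledger_path, index=False)

    comps = []
    for on_spec, off_spec in pairs:
        k_on = _ledger_ks(ledger, on_spec)
        k_off = _ledger_ks(ledger, off_spec)
        c = wilcoxon_compare(k_on, k_off)
        comps.append({
            "config_hash_on": on_spec.config_hash(),
            "config_hash_off": off_spec.config_hash(),
            "n_neurons": on_spec.n_neurons, "nb": on_spec.nb, "rp": on_spec.rp,
            "omega": on_spec.omega, "inhib_fraction": on_spec.inhib_fraction,
            "mean_K_on": float(np.mean(k_on)), "mean_K_off": float(np.mean(k_off)),
            "statistic": c.statistic, "p_value": c.p_value, "stars": c.stars,
        })
    comparisons = pd.DataFrame(comps)
    if ledger_path:
        comparisons.to_csv(out_dir / "comparisons.csv", index=False)
    return ledger, comparisons


def _ledger_ks(ledger: pd.DataFrame, spec: ConditionSpec) -> np.ndarray:
    h = spec.config_hash()
    sub = ledger[(ledger["config_hash"] == h) & ledger["seed"].isin(spec.seeds)]
    if len(sub) != spec.n_seeds:
        raise RuntimeError(f"ledger incomplete for condition {h}: "
                           f"{len(sub)}/{spec.n_seeds} seeds present")
    return sub.sort_values("seed")["K"].to_numpy()


# ---------------------------------------------------------------------------
# shipped grids (the published comparison sweeps)

def _pairs(values, key, **overrides):
    base = ConditionSpec(**overrides)
    return [replace(base, **{key: v}).paired() for v in values]


def grid_rewiring(rps=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
                  **overrides):
    """Complexity vs rewiring probability at N=100, omega=5 (decade grid)."""
    return _pairs(rps, "rp", **overrides)


def grid_network_size(sizes=(50, 100, 150, 200), **overrides):
    """Complexity vs network size at rp=0.1, omega=5."""
    return _pairs(sizes, "n_neurons", **overrides)


def grid_synaptic_intensity(omegas=(5.0, 10.0, 15.0, 20.0, 30.0), **overrides):
    """Complexity vs synaptic intensity at N=100, rp=0.1."""
    return _pairs(omegas, "omega", **overrides)


def grid_neighborhood(nbs=(4, 12), omega: float = 5.0, n_neurons: int = 200,
                      **overrides):
    """Complexity vs neighbourhood size nb at N=200, for one omega."""
    return _pairs(nbs, "nb", omega=omega, n_neurons=n_neurons, **overrides)


def load_grid(path):
    """Load a sweep grid from a YAML file.

    Schema: top-level keys are ConditionSpec fields; an optional ``sweep``
    mapping gives one field name to a list of values.  Each value yields an
    (ephaptic-on, ephaptic-off) pair.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sweep_block = doc.pop("sweep", None)
    base = ConditionSpec(**doc)
    if not sweep_block:
        return [base.paired()]
    (key, values), = sweep_block.items()
    return [replace(base, **{key: v}).paired() for v in values]
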