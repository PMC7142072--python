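"""Statistical model checking engine (SMCE).

Calibration machinery that treats each candidate parameter vector as a
probabilistic model: central values on a search grid are wrapped in
uniform uncertainty intervals (+/- a pseudo standard deviation), random
realizations are simulated, and the probability Theta that a realization
stays inside the observation tunnels is estimated by Monte Carlo.  With n
simulations the estimate carries a Chernoff-Hoeffding style precision
epsilon at error rate delta, and a Wald sequential probability ratio test
prunes candidates whose match probability provably cannot reach the
acceptance threshold gamma before all n simulations are spent.  Accepted
candidates (Theta > gamma) are ranked by a combined lab + in-situ error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Trajectory, simulate_ensemble
from .morphometry import bd_from_cm, cm_from_bd
from .params import SEARCHED_PARAMETERS, ParameterSet, p_max_from_kp
from .tunnels import TunnelSet

__all__ = [
    "SearchVector",
    "CandidateVector",
    "SMCConfig",
    "EvaluationResult",
    "enumerate_space",
    "space_size",
    "perturb",
    "check_tunnel",
    "SprtTest",
    "sprt_decide",
    "chernoff_n",
    "estimate_match",
    "evaluate_space",
    "results_table",
    "correlogram",
]


# ---------------------------------------------------------------------------
# search space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchVector:
    """Inclusive arithmetic grid [lo : step : hi] in native units."""

    lo: float
    step: float
    hi: float

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.hi < self.lo:
            raise ValueError("hi must not be below lo")

    def __len__(self) -> int:
        # index-generated inclusive count; the epsilon absorbs float drift
        # in (hi - lo) / step without ever overshooting hi by a full step.
        return int(math.floor((self.hi - self.lo) / self.step + 1e-6)) + 1

    def values(self) -> np.ndarray:
        return self.lo + self.step * np.arange(len(self))


@dataclass(frozen=True)
class CandidateVector:
    """Central values on the grid plus per-parameter pseudo stds."""

    center: dict
    pseudo_std: dict
    index: int = 0

    def __post_init__(self):
        for name, std in self.pseudo_std.items():
            if std < 0:
                raise ValueError(f"pseudo_std[{name!r}] must be non-negative")


def space_size(search_vectors: dict) -> int:
    """Number of candidates in the Cartesian product (no enumeration)."""
    if not search_vectors:
        raise ValueError("at least one search vector is required")
    n = 1
    for vec in search_vectors.values():
        n *= len(vec)
    return n


def enumerate_space(search_vectors: dict, pseudo_std: dict | None = None):
    """Lazily yield the lexicographic Cartesian product of the grids.

    Parameter order follows the canonical searched-parameter order for
    known names, then insertion order for any extras; the candidate index
    is its position in the enumeration.
    """
    if not search_vectors:
        raise ValueError("at least one search vector is required")
    names = [p for p in SEARCHED_PARAMETERS if p in search_vectors]
    names += [p for p in search_vectors if p not in names]
    grids = [search_vectors[p].values() for p in names]
    pseudo_std = pseudo_std or {}
    sizes = [len(g) for g in grids]
    total = int(np.prod(sizes))
    for idx in range(total):
        rem, center = idx, {}
        for name, grid, size in zip(reversed(names), reversed(grids),
                                    reversed(sizes)):
            center[name] = float(grid[rem % size])
            rem //= size
        center = {n: center[n] for n in names}
        yield CandidateVector(center=center,
                              pseudo_std={n: pseudo_std.get(n, 0.0)
                                          for n in names},
                              index=idx)


def perturb(candidate: CandidateVector, rng: np.random.Generator,
            base: ParameterSet | None = None, size: int | None = None) -> dict:
    """Draw a concrete realization from the candidate's uncertainty box.

    Each searched parameter is drawn uniformly from
    [max(0, center - std), center + std] (a_max additionally capped at 1),
    and p_max is recomputed from the drawn k_p.  With ``size`` given, all
    draws are vectorized arrays; parameters are consumed in canonical
    order so the random stream is reproducible.
    """
    base = base or ParameterSet()
    out = {}
    for name in candidate.center:
        c = candidate.center[name]
        s = candidate.pseudo_std.get(name, 0.0)
        lo, hi = max(0.0, c - s), c + s
        if name == "a_max":
            hi = min(1.0, hi)
            lo = min(lo, hi)
        if hi <= lo:
            out[name] = np.full(size, lo) if size is not None else lo
        else:
            out[name] = rng.uniform(lo, hi, size)
    if "k_p" in out:
        out["p_max"] = p_max_from_kp(np.asarray(out["k_p"]), base.F_sat) \
            if size is not None else p_max_from_kp(out["k_p"], base.F_sat)
    return out


# ---------------------------------------------------------------------------
# tunnel comparison
# ---------------------------------------------------------------------------

def _band_distances(values: np.ndarray, tunnel: TunnelSet):
    """Inside flags and mean normalized excursions for (m, n_times) values.

    NaN values (trajectory truncated before that observation time) count
    as outside with a one-half-width excursion.
    """
    lower, upper = tunnel.lower, tunnel.upper
    hw = tunnel.half_width
    denom = np.where(hw > 0, hw, 1.0)
    below = np.clip(lower - values, 0.0, None)
    above = np.clip(values - upper, 0.0, None)
    exc = (below + above) / denom
    missing = np.isnan(values)
    exc = np.where(missing, 1.0, exc)
    inside = ~np.any((exc > 0) | missing, axis=-1)
    return inside, exc.mean(axis=-1)


def check_tunnel(trajectory: Trajectory, tunnel: TunnelSet):
    """Does a trajectory fit inside the observation tunnel?

    Returns ``(inside, dist)``: inside is True iff the compared variable
    lies within [lower, upper] at every tunnel time (linear interpolation
    between model steps); dist is the mean over tunnel times of the
    excursion beyond the nearest bound, normalized by the local tunnel
    half-width (0 when fully inside).
    """
    values = trajectory.values_at(tunnel.times, tunnel.variable)
    inside, dist = _band_distances(values[None, :], tunnel)
    return bool(inside[0]), float(dist[0])


# ---------------------------------------------------------------------------
# sequential probability ratio test
# ---------------------------------------------------------------------------

def chernoff_n(epsilon: float, delta: float) -> int:
    """Sample size for |Theta - P| <= epsilon w.p. >= 1 - delta."""
    return int(math.ceil(math.log(2.0 / delta) / (2.0 * epsilon ** 2)))


class SprtTest:
    """Wald SPRT of H0: p >= gamma+epsilon against H1: p <= gamma-epsilon.

    Used one-sidedly: the test only ever *rejects* a candidate (evidence
    that its match probability cannot reach the threshold); it never
    accepts early, so estimation otherwise runs to the full budget.
    Both error rates are delta.
    """

    def __init__(self, gamma: float, epsilon: float, delta: float):
        p0, p1 = gamma + epsilon, gamma - epsilon
        if not (0.0 < p1 and p0 < 1.0):
            raise ValueError("gamma +/- epsilon must lie strictly in (0, 1)")
        self.llr = 0.0
        self.boundary = math.log((1.0 - delta) / delta)
        self._inc_pass = math.log(p1 / p0)
        self._inc_fail = math.log((1.0 - p1) / (1.0 - p0))
        self.decision = "continue"

    def update(self, passed: bool) -> str:
        if self.decision != "continue":
            return self.decision
        self.llr += self._inc_pass if passed else self._inc_fail
        if self.llr >= self.boundary:
            self.decision = "reject_below_threshold"
        return self.decision


def sprt_decide(stream, gamma: float, epsilon: float, delta: float):
    """Run the SPRT over a pass/fail stream.

    Returns ``(decision, n_consumed)`` where decision is
    'reject_below_threshold' as soon as the likelihood-ratio boundary is
    crossed, or 'complete' when the stream ends undecided.
    """
    test = SprtTest(gamma, epsilon, delta)
    n = 0
    for passed in stream:
        n += 1
        if test.update(bool(passed)) == "reject_below_threshold":
            return "reject_below_threshold", n
    return "complete", n


# ---------------------------------------------------------------------------
# candidate evaluation
# ---------------------------------------------------------------------------

@dataclass
class SMCConfig:
    """Monte Carlo / SPRT settings.

    Defaults follow the study configuration: 500 simulations per candidate
    for a 5% estimation precision at a 1% error rate, acceptance threshold
    Match > 70%.
    """

    n_sims: int = 500
    epsilon: float = 0.05
    delta: float = 0.01
    gamma: float = 0.70
    rng_seed: int = 0
    chunk_size: int = 25
    use_sprt: bool = True  # False: always run the full Monte Carlo budget

    def __post_init__(self):
        for name in ("epsilon", "delta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_sims < 1 or self.chunk_size < 1:
            raise ValueError("n_sims and chunk_size must be >= 1")


@dataclass
class EvaluationResult:
    """Outcome of evaluating one candidate against the scenarios.

    ``score`` holds, per scenario, the fraction of simulations that fell
    outside that scenario's tunnel; ``dist`` the mean normalized distance
    to the tunnel.  ``theta_hat`` estimates the probability that a random
    realization fits *all* scenarios simultaneously, so when every
    simulation ran, 1 - theta_hat equals the fraction outside overall.
    """

    candidate: CandidateVector
    theta_hat: float
    score: dict
    dist: dict
    decided_by: str  # 'monte_carlo' | 'sprt_reject' | 'failed'
    n_used: int
    retained: bool = False

    @property
    def mean_dist(self) -> float:
        return float(np.mean(list(self.dist.values())))


class _CandidateState:
    __slots__ = ("candidate", "rng", "sprt", "use_sprt", "n_used", "n_pass",
                 "fail_counts", "dist_sums", "done", "decided_by")

    def __init__(self, candidate, master_seed, config, scenario_names):
        self.candidate = candidate
        self.rng = np.random.default_rng(
            np.random.SeedSequence([int(master_seed), int(candidate.index)]))
        self.sprt = SprtTest(config.gamma, config.epsilon, config.delta)
        self.use_sprt = config.use_sprt
        self.n_used = 0
        self.n_pass = 0
        self.fail_counts = {s: 0 for s in scenario_names}
        self.dist_sums = {s: 0.0 for s in scenario_names}
        self.done = False
        self.decided_by = "monte_carlo"

    def absorb(self, inside_by_scenario, dist_by_scenario, n_sims):
        """Feed one chunk of per-draw results through the SPRT in order."""
        names = list(inside_by_scenario)
        chunk = len(inside_by_scenario[names[0]])
        for j in range(chunk):
            overall = all(bool(inside_by_scenario[s][j]) for s in names)
            self.n_used += 1
            self.n_pass += int(overall)
            for s in names:
                self.fail_counts[s] += int(not inside_by_scenario[s][j])
                self.dist_sums[s] += float(dist_by_scenario[s][j])
            if self.use_sprt and \
                    self.sprt.update(overall) == "reject_below_threshold":
                self.done = True
                self.decided_by = "sprt_reject"
                return
        if self.n_used >= n_sims:
            self.done = True

    def result(self, gamma) -> EvaluationResult:
        n = max(self.n_used, 1)
        theta = self.n_pass / n
        return EvaluationResult(
            candidate=self.candidate,
            theta_hat=theta,
            score={s: c / n for s, c in self.fail_counts.items()},
            dist={s: d / n for s, d in self.dist_sums.items()},
            decided_by=self.decided_by,
            n_used=self.n_used,
            retained=(self.decided_by == "monte_carlo" and theta > gamma),
        )


def _scenario_eval(scenario, draws, base: ParameterSet):
    """Simulate one chunk of draws through a scenario and check its tunnel."""
    m = len(next(iter(draws.values())))
    cm0 = np.full(m, cm_from_bd(scenario.initial_bd))
    overrides = {k: np.asarray(v) for k, v in draws.items()
                 if k in ("p_max", "k_p", "a_max", "k_a", "c_re", "spn", "c_e")}
    F_draws = None
    if scenario.f_lab_driven:
        if "F_lab" not in draws:
            raise ValueError(
                f"scenario {scenario.name!r} needs F_lab among the draws")
        F_draws = np.asarray(draws["F_lab"])
    cm, _alive = simulate_ensemble(cm0, scenario.forcing, base, overrides,
                                   F_draws)
    tun = scenario.tunnel
    # linear interpolation of the compared variable at tunnel times
    t = scenario.forcing.t
    idx = np.clip(np.searchsorted(t, tun.times, side="right") - 1, 0,
                  len(t) - 2)
    w = (tun.times - t[idx]) / (t[idx + 1] - t[idx])
    vals = (1.0 - w) * cm[:, idx] + w * cm[:, idx + 1]
    if tun.variable == "bd":
        valid = np.isfinite(vals) & (vals > 0)
        bd = np.full_like(vals, np.nan)
        bd[valid] = bd_from_cm(vals[valid])
        vals = bd
    return _band_distances(vals, tun)


def evaluate_space(candidates, scenarios, base: ParameterSet,
                   config: SMCConfig):
    """Evaluate every candidate against all scenarios.

    Candidates are independent: each owns a random stream seeded from
    (master seed, candidate grid index), so results do not depend on
    evaluation order or batching across candidates.  Simulation work is
    vectorized across the active candidates' chunks.  Returns one
    :class:`EvaluationResult` per candidate, in input order.
    """
    candidates = list(candidates)
    names = [s.name for s in scenarios]
    states = [_CandidateState(c, config.rng_seed, config, names)
              for c in candidates]
    active = list(range(len(states)))
    while active:
        chunk_draws, spans = [], []
        pos = 0
        for i in active:
            st = states[i]
            k = min(config.chunk_size, config.n_sims - st.n_used)
            d = perturb(st.candidate, st.rng, base, size=k)
            chunk_draws.append(d)
            spans.append((i, pos, pos + k))
            pos += k
        merged = {key: np.concatenate([np.asarray(d[key], dtype=float)
                                       for d in chunk_draws])
                  for key in chunk_draws[0]}
        inside_all, dist_all = {}, {}
        for sc in scenarios:
            inside, dist = _scenario_eval(sc, merged, base)
            inside_all[sc.name], dist_all[sc.name] = inside, dist
        for i, a, b in spans:
            states[i].absorb({s: inside_all[s][a:b] for s in names},
                             {s: dist_all[s][a:b] for s in names},
                             config.n_sims)
        active = [i for i in active if not states[i].done]
    return [st.result(config.gamma) for st in states]


def estimate_match(candidate: CandidateVector, scenarios,
                   base: ParameterSet, config: SMCConfig) -> EvaluationResult:
    """Monte Carlo match-probability estimate for a single candidate."""
    return evaluate_space([candidate], scenarios, base, config)[0]


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def results_table(results, scenarios=None) -> pd.DataFrame:
    """Flat per-candidate results table (one row per candidate)."""
    rows = []
    for r in results:
        row = {"candidate_index": r.candidate.index}
        row.update(r.candidate.center)
        row["theta_hat"] = r.theta_hat
        for s, v in r.score.items():
            row[f"score_{s}"] = v
        for s, v in r.dist.items():
            row[f"dist_{s}"] = v
        row["dist"] = r.mean_dist
        row["decided_by"] = r.decided_by
        row["n_used"] = r.n_used
        row["retained"] = r.retained
        rows.append(row)
    return pd.DataFrame(rows)


def correlogram(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Spearman rank-correlation matrix between parameters and outputs.

    Requires at least 3 rows (accepted candidates).  Constant columns have
    undefined rank correlation and are reported as NaN, never as zero.
    """
    if len(table) < 3:
        raise ValueError("correlogram needs at least 3 accepted candidates")
    cols = columns or [c for c in table.columns
                       if table[c].dtype.kind in "fiu"]
    sub = table[cols].astype(float)
    corr = sub.corr(method="spearman")
    # pandas pins the diagonal at 1 even for constant columns; undefined
    # self-correlation must stay missing.
    for c in cols:
        if sub[c].nunique() <= 1:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
    return corr
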