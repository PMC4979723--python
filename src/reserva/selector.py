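"""Minimum-set reserve selection by simulated annealing.

This is a from-scratch implementation of the classic Marxan-style problem:
choose a set of planning units that meets every feature's conservation
target at minimum total cost.  The objective is

    score(S) = Σ_{i∈S} cost_i
             + Σ_f spf_f · cost_scale · max(0, target_f − achieved_f(S)) / target_f
             + blm · boundary(S)

where ``achieved_f(S)`` is the feature amount inside S, the shortfall is
normalized by the target so small-range features are not dominated by
widespread ones, and ``cost_scale`` converts the dimensionless shortfall
into cost units (mean PU cost × a PUs-needed heuristic; see
:func:`penalty_cost_scale`).  Locked-in PUs belong to every solution;
locked-out PUs to none, and their amounts are never creditable.

Replicate runs with consecutive seeds give a *summed solution* — the
per-PU selection frequency, a proxy for irreplaceability — thresholded
into priority areas.  An exhaustive enumerator doubles as an independent
optimum oracle on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, exp

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .landscape import FeatureAmountMatrix, PlanningUnitSet
from .targets import MET_RTOL

__all__ = [
    "SelectionProblem",
    "AnnealSchedule",
    "Solution",
    "SummedSolution",
    "objective",
    "anneal",
    "brute_force_optimum",
    "summed_solution",
    "priority_areas",
    "greedy_add_baseline",
]

DEFAULT_SPF = 10.0


def penalty_cost_scale(cost: np.ndarray, area: np.ndarray,
                       target_km2: np.ndarray) -> float:
    """Cost units per unit of normalized shortfall.

    Documented constant formula: mean PU cost times the number of PUs a
    solution plausibly needs, estimated as the largest single-feature target
    divided by the mean PU area.  With the default spf of 10 this prices one
    fully unmet feature at ten times that estimated solution cost.
    """
    mean_cost = float(np.mean(cost)) if len(cost) else 1.0
    mean_area = float(np.mean(area)) if len(area) else 1.0
    biggest = float(np.max(target_km2)) if len(target_km2) else mean_area
    pus_needed = max(1, ceil(biggest / max(mean_area, 1e-12)))
    return mean_cost * pus_needed


@dataclass
class SelectionProblem:
    """A prepared minimum-set instance.

    Built from locked planning units, the feature-amount matrix and a target
    table; precomputes sparse per-PU feature columns for O(features-per-PU)
    move evaluation.
    """

    pus: PlanningUnitSet
    amounts: FeatureAmountMatrix
    targets: pd.DataFrame
    spf: np.ndarray = None  # per-feature penalty factor
    blm: float = 0.0

    def __post_init__(self) -> None:
        n_f = self.amounts.n_features
        if self.spf is None:
            self.spf = np.full(n_f, DEFAULT_SPF)
        else:
            self.spf = np.broadcast_to(np.asarray(self.spf, dtype=float), (n_f,)).copy()
        if (self.spf <= 0).any():
            raise ValueError("species penalty factors must be positive")
        if (self.pus.cost <= 0).any():
            raise ValueError("PU costs must be strictly positive")
        self.target_km2 = self.targets["target_km2"].to_numpy(dtype=float)
        if (self.target_km2 <= 0).any():
            raise ValueError("target amounts must be positive")
        self.cost_scale = penalty_cost_scale(self.pus.cost, self.pus.area, self.target_km2)
        self.locked_in = self.pus.locked_in
        self.locked_out = self.pus.locked_out
        self.available_ids = np.nonzero(self.pus.available)[0]
        # locked-out PUs carry no selectable amount
        amt = self.amounts.amount.copy()
        amt[:, self.locked_out] = 0.0
        self._csc = sp.csc_matrix(amt)
        self.base_achieved = amt[:, self.locked_in].sum(axis=1)

    # -- incremental machinery ----------------------------------------

    def feature_column(self, pu: int) -> tuple[np.ndarray, np.ndarray]:
        """(feature indices, amounts) held by one PU."""
        s, e = self._csc.indptr[pu], self._csc.indptr[pu + 1]
        return self._csc.indices[s:e], self._csc.data[s:e]

    def achieved(self, selected: np.ndarray) -> np.ndarray:
        """Per-feature km² inside the selection (locked-in included)."""
        sel = np.asarray(selected, dtype=bool) | self.locked_in
        return np.asarray(self._csc[:, sel].sum(axis=1)).ravel()

    def shortfall_penalty(self, achieved: np.ndarray) -> float:
        short = np.maximum(0.0, self.target_km2 - achieved) / self.target_km2
        return float(np.dot(self.spf, short)) * self.cost_scale

    def boundary_length(self, selected: np.ndarray) -> float:
        if self.blm == 0.0 or not self.pus.adjacency:
            return 0.0
        sel = np.asarray(selected, dtype=bool) | self.locked_in
        return sum(l for (i, j), l in self.pus.adjacency.items() if sel[i] != sel[j])

    def met(self, achieved: np.ndarray) -> np.ndarray:
        return achieved >= self.target_km2 * (1 - MET_RTOL)


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule.

    ``t_init=None`` sets the initial temperature adaptively from sampled
    move deltas (5 × mean |Δ|, so typical worsening moves start near 80%
    acceptance); cooling runs to ``t_init × t_final_frac`` over ``n_iter``
    single-PU flip proposals.
    """

    n_iter: int = 1_000_000
    t_init: float | None = None
    t_final_frac: float = 1e-6
    init_select_prob: float = 0.5


@dataclass
class Solution:
    selected: np.ndarray  # boolean over PUs, ⊇ locked_in, ∩ locked_out = ∅
    objective: float
    achieved: np.ndarray
    met: np.ndarray

    @property
    def selected_ids(self) -> np.ndarray:
        return np.nonzero(self.selected)[0]

    @property
    def all_met(self) -> bool:
        return bool(self.met.all())


@dataclass
class SummedSolution:
    frequency: np.ndarray  # per-PU count in 0..n_reps
    n_reps: int
    priority_threshold: int = 75
    best: "Solution | None" = None  # lowest-objective replicate


def objective(problem: SelectionProblem, selected: np.ndarray) -> float:
    """Full recomputation of the objective for a selection."""
    sel = np.asarray(selected, dtype=bool) | problem.locked_in
    if (sel & problem.locked_out).any():
        raise ValueError("selection includes locked-out planning units")
    cost = float(problem.pus.cost[sel].sum())
    achieved = problem.achieved(sel)
    score = cost + problem.shortfall_penalty(achieved)
    if problem.blm:
        score += problem.blm * problem.boundary_length(sel)
    return score


def _solution_from(problem: SelectionProblem, sel: np.ndarray) -> Solution:
    achieved = problem.achieved(sel)
    return Solution(
        selected=sel,
        objective=objective(problem, sel),
        achieved=achieved,
        met=problem.met(achieved),
    )


def anneal(
    problem: SelectionProblem,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
) -> Solution:
    """Simulated annealing over single-PU add/remove flips.

    Starts from a seeded random subset of the available PUs, accepts
    improving moves always and worsening moves with probability
    exp(−Δ/T) under geometric cooling, then runs a greedy pass that
    removes any PU whose removal lowers the objective.  Deterministic for
    a fixed seed.  If targets are unreachable even selecting every
    available PU, the returned solution simply flags the unmet features.
    """
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    avail = problem.available_ids
    n = problem.pus.n_pus

    sel = problem.locked_in.copy()
    if len(avail):
        sel[avail] = rng.random(len(avail)) < schedule.init_select_prob

    achieved = problem.achieved(sel)
    short = np.maximum(0.0, problem.target_km2 - achieved) / problem.target_km2
    pen_w = problem.spf * problem.cost_scale  # per-feature penalty weight
    cost_sum = float(problem.pus.cost[sel].sum())
    use_blm = problem.blm != 0.0
    # neighbor lists only materialized when the boundary term is active
    if use_blm:
        nbrs: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
        for (i, j), l in problem.pus.adjacency.items():
            nbrs[i].append((j, l))
            nbrs[j].append((i, l))
        boundary = problem.boundary_length(sel)

    def flip_delta(pu: int, adding: bool) -> tuple[float, np.ndarray, np.ndarray]:
        fidx, famt = problem.feature_column(pu)
        new_ach = achieved[fidx] + (famt if adding else -famt)
        new_short = np.maximum(0.0, problem.target_km2[fidx] - new_ach) / problem.target_km2[fidx]
        d = float(np.dot(pen_w[fidx], new_short - short[fidx]))
        d += problem.pus.cost[pu] if adding else -problem.pus.cost[pu]
        if use_blm:
            db = 0.0
            for j, l in nbrs[pu]:
                db += -l if sel[j] else l
            d += problem.blm * (db if adding else -db)
        return d, fidx, new_ach

    def commit(pu: int, adding: bool, fidx: np.ndarray, new_ach: np.ndarray) -> None:
        nonlocal cost_sum
        achieved[fidx] = new_ach
        short[fidx] = np.maximum(0.0, problem.target_km2[fidx] - new_ach) / problem.target_km2[fidx]
        cost_sum += problem.pus.cost[pu] if adding else -problem.pus.cost[pu]
        sel[pu] = adding

    if len(avail):
        # adaptive initial temperature from sampled move deltas
        if schedule.t_init is None:
            probe = rng.choice(avail, size=min(64, len(avail)), replace=True)
            deltas = [abs(flip_delta(int(p), not sel[p])[0]) for p in probe]
            t0 = 5.0 * (float(np.mean(deltas)) or 1.0)
        else:
            t0 = schedule.t_init
        t0 = max(t0, 1e-12)
        alpha = schedule.t_final_frac ** (1.0 / max(schedule.n_iter, 1))

        # incumbent tracking: the walk may visit the optimum and drift off
        # before the temperature pins it, so keep the best state ever seen
        cur_obj = cost_sum + float(np.dot(pen_w, short))
        if use_blm:
            cur_obj += problem.blm * boundary
        best_obj, best_sel = cur_obj, sel.copy()

        temp = t0
        picks = rng.integers(0, len(avail), size=schedule.n_iter)
        us = rng.random(schedule.n_iter)
        for k in range(schedule.n_iter):
            pu = int(avail[picks[k]])
            adding = not sel[pu]
            d, fidx, new_ach = flip_delta(pu, adding)
            if d < 0 or (temp > 0 and us[k] < exp(min(0.0, -d / temp))):
                commit(pu, adding, fidx, new_ach)
                cur_obj += d
                if cur_obj < best_obj - 1e-12:
                    best_obj, best_sel = cur_obj, sel.copy()
            temp *= alpha

        def greedy_prune(state: np.ndarray) -> np.ndarray:
            """Drop any PU whose removal lowers the objective (never raises it)."""
            nonlocal achieved, short, cost_sum, sel
            sel = state
            achieved = problem.achieved(sel)
            short = np.maximum(0.0, problem.target_km2 - achieved) / problem.target_km2
            cost_sum = float(problem.pus.cost[sel].sum())
            improved = True
            while improved:
                improved = False
                for pu in avail[sel[avail]]:
                    d, fidx, new_ach = flip_delta(int(pu), adding=False)
                    if d < -1e-12:
                        commit(int(pu), False, fidx, new_ach)
                        improved = True
            return sel

        final = greedy_prune(sel.copy())
        final_obj = objective(problem, final)
        incumbent = greedy_prune(best_sel.copy())
        incumbent_obj = objective(problem, incumbent)
        sel = final if final_obj <= incumbent_obj else incumbent

    return _solution_from(problem, sel)


def brute_force_optimum(problem: SelectionProblem, max_available: int = 20) -> Solution:
    """Exact minimizer by exhaustive enumeration (independent oracle).

    Enumerates all 2^n lock-respecting subsets of the available PUs;
    ties on the objective are broken by the lexicographically smallest
    sorted tuple of selected PU ids.
    """
    avail = problem.available_ids
    n = len(avail)
    if n > max_available:
        raise ValueError(f"{n} available PUs exceeds enumeration limit {max_available}")
    avail_amt = np.asarray(problem._csc[:, avail].todense())  # (F, n)
    avail_cost = problem.pus.cost[avail]
    base_cost = float(problem.pus.cost[problem.locked_in].sum())
    pen_w = problem.spf * problem.cost_scale
    tgt = problem.target_km2

    # enumerate every subset at once: column s of `bits` is subset s's
    # indicator over the available PUs
    n_sub = 1 << n
    bits = ((np.arange(n_sub)[None, :] >> np.arange(n)[:, None]) & 1).astype(float)
    achieved = problem.base_achieved[:, None] + avail_amt @ bits
    short = np.maximum(0.0, tgt[:, None] - achieved) / tgt[:, None]
    scores = base_cost + avail_cost @ bits + pen_w @ short
    if problem.blm:
        for s in range(n_sub):
            sel = problem.locked_in.copy()
            sel[avail[bits[:, s] > 0]] = True
            scores[s] += problem.blm * problem.boundary_length(sel)

    lowest = scores.min()
    cand = np.nonzero(scores <= lowest + 1e-12)[0]
    best_key, best_s = None, None
    for s in cand:
        sel = problem.locked_in.copy()
        sel[avail[bits[:, s] > 0]] = True
        key = tuple(np.nonzero(sel)[0].tolist())
        if best_key is None or key < best_key:
            best_key, best_s = key, s
    sel = problem.locked_in.copy()
    sel[avail[bits[:, best_s] > 0]] = True
    return _solution_from(problem, sel)


def greedy_add_baseline(problem: SelectionProblem) -> Solution:
    """Cheapest-shortfall-reduction greedy construction (comparison baseline)."""
    sel = problem.locked_in.copy()
    achieved = problem.achieved(sel)
    avail = set(int(i) for i in problem.available_ids)
    while not problem.met(achieved).all() and avail:
        best_pu, best_gain = None, 0.0
        short = np.maximum(0.0, problem.target_km2 - achieved) / problem.target_km2
        for pu in avail:
            fidx, famt = problem.feature_column(pu)
            new_short = np.maximum(0.0, problem.target_km2[fidx] - achieved[fidx] - famt) \
                / problem.target_km2[fidx]
            gain = float(np.dot(problem.spf[fidx], short[fidx] - new_short)) * problem.cost_scale
            ratio = gain / problem.pus.cost[pu]
            if ratio > best_gain:
                best_gain, best_pu = ratio, pu
        if best_pu is None:
            break
        fidx, famt = problem.feature_column(best_pu)
        achieved[fidx] += famt
        sel[best_pu] = True
        avail.discard(best_pu)
    return _solution_from(problem, sel)


def summed_solution(
    problem: SelectionProblem,
    n_reps: int = 100,
    base_seed: int = 0,
    schedule: AnnealSchedule | None = None,
    priority_threshold: int = 75,
) -> SummedSolution:
    """Selection frequency over ``n_reps`` independent annealing replicates
    seeded ``base_seed + k``; also keeps the best (lowest-objective) replicate."""
    freq = np.zeros(problem.pus.n_pus, dtype=int)
    best: Solution | None = None
    for k in range(n_reps):
        sol = anneal(problem, schedule=schedule, seed=base_seed + k)
        freq += sol.selected
        if best is None or sol.objective < best.objective:
            best = sol
    return SummedSolution(frequency=freq, n_reps=n_reps,
                          priority_threshold=priority_threshold, best=best)


def priority_areas(ss: SummedSolution, threshold: int | None = None) -> np.ndarray:
    """PUs selected in at least ``threshold`` replicates (inclusive)."""
    t = ss.priority_threshold if threshold is None else threshold
    return ss.frequency >= t
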