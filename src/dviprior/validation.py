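"""Cross-validation model selection: Discriminating Power and Efficacy Rate.

One *realization* splits the solved cases D at random into a learning
sample D_L (default 75%) and a reserved sample D_V.  The reserved cases
are pretended unidentified: they are re-inserted into the candidate set
(V grows to N' = N + #D_V and their cells' N_j grow accordingly), the
model is fitted on D_L alone, and every candidate of the augmented set
is scored.  Against the uniform baseline 1/N' — the score every
candidate has before any solved case is observed — two metrics are
computed per realization:

* Discriminating Power  DP = R+ / R: the fraction of the R reserved
  cases whose score strictly exceeds the baseline;
* Efficacy Rate         E = R+ / N+: the reserved cases that improved,
  relative to *all* N+ candidates that improved.  E = 0 when N+ = 0.

A useless model scores like a random ranking on both.  Averaging DP and
E over many realizations (typically 50) for every candidate partition —
variable subsets crossed with a grid of temporal window lengths T —
selects the most informative partition of the non-genetic variables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import ScoreTable, fit_scores
from .errors import ElicitationError, SplitError
from .io import Roster
from .partition import PartitionSpec, build_cell_table

#: Temporal window lengths (days) scanned by default: 1..90 in steps of 3.
DEFAULT_T_GRID = tuple(range(1, 91, 3))
DEFAULT_N_REALIZATIONS = 50
DEFAULT_SPLIT_FRACTION = 0.75


@dataclass(frozen=True)
class CVRealization:
    """One random split of the solved cases into learning / reserved."""

    seed: int
    learning_ids: frozenset[str]
    reserved_ids: frozenset[str]
    split_fraction: float

    def __post_init__(self):
        if self.learning_ids & self.reserved_ids:
            raise ValueError("learning and reserved sets overlap")
        if not self.learning_ids or not self.reserved_ids:
            raise ValueError("learning and reserved sets must be non-empty")


@dataclass(frozen=True)
class ValidationResult:
    """Per-realization DP/E records plus their aggregates."""

    realizations: pd.DataFrame  # seed, R, R_plus, N_plus, DP, E
    mean_DP: float
    mean_E: float
    sd_DP: float
    sd_E: float
    n_ok: int
    n_failed: int


def realization_seed(master_seed: int, index: int) -> int:
    """Deterministic per-realization seed below 2**31.

    Child i of master seed s is the first state word of
    ``numpy.random.SeedSequence(s, spawn_key=(i,))`` reduced mod 2**31.
    """
    seq = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(seq.generate_state(1)[0] % (2**31))


def split_solved(
    roster: Roster,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    seed: int = 0,
) -> CVRealization:
    """Random partition of D without replacement.

    The learning-set size is round-half-to-even of
    ``split_fraction * n_s`` and both sides must be non-empty.
    """
    n_s = roster.n_solved
    if n_s < 2:
        raise SplitError(f"need at least 2 solved cases to split, have {n_s}")
    if not 0.0 < split_fraction < 1.0:
        raise SplitError(f"split_fraction must be in (0, 1), got {split_fraction}")
    n_learning = round(split_fraction * n_s)
    if n_learning < 1 or n_learning > n_s - 1:
        raise SplitError(
            f"split_fraction={split_fraction} leaves an empty learning or "
            f"reserved set for n_s={n_s}"
        )
    ids = sorted(r.victim_id for r in roster.identified)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    learning = frozenset(ids[i] for i in perm[:n_learning])
    reserved = frozenset(ids[i] for i in perm[n_learning:])
    return CVRealization(
        seed=seed,
        learning_ids=learning,
        reserved_ids=reserved,
        split_fraction=split_fraction,
    )


def _augmented_roster(roster: Roster, realization: CVRealization) -> Roster:
    """Move the reserved solved cases back into the candidate set."""
    moved = tuple(
        _dc_replace(rec, status="candidate")
        for rec in roster.identified
        if rec.victim_id in realization.reserved_ids
    )
    if len(moved) != len(realization.reserved_ids):
        missing = realization.reserved_ids - {r.victim_id for r in moved}
        raise SplitError(f"reserved ids not found among solved cases: {sorted(missing)}")
    kept = tuple(
        rec for rec in roster.identified
        if rec.victim_id in realization.learning_ids
    )
    if len(kept) != len(realization.learning_ids):
        missing = realization.learning_ids - {r.victim_id for r in kept}
        raise SplitError(f"learning ids not found among solved cases: {sorted(missing)}")
    return _dc_replace(
        roster, candidates=roster.candidates + moved, identified=kept
    )


def score_realization(
    roster: Roster, spec: PartitionSpec, realization: CVRealization
) -> ScoreTable:
    """Fit on the learning sample and score the augmented candidate set.

    The reserved cases enter V (their cells' N_j incremented, their own
    I_j contributions removed); only the learning cases drive the
    posterior update.  Propagates :class:`ElicitationError` when the
    augmented counts make the CV=1 prior infeasible.
    """
    augmented = _augmented_roster(roster, realization)
    table = build_cell_table(augmented, spec)
    return fit_scores(table)


def dp_and_e(
    scores: ScoreTable, realization: CVRealization, baseline: float
) -> tuple[float, float, int, int, int]:
    """Discriminating Power and Efficacy Rate for one realization.

    ``baseline`` is 1/N' on the augmented candidate set.  "Improves"
    means strictly greater than the baseline; a tie does not count.

    Returns ``(DP, E, R, R_plus, N_plus)``.
    """
    frame = scores.scores
    improved = frame["score"].to_numpy() > baseline
    n_plus = int(improved.sum())
    reserved_mask = frame["victim_id"].isin(realization.reserved_ids).to_numpy()
    r = len(realization.reserved_ids)
    r_plus = int((improved & reserved_mask).sum())
    dp = r_plus / r
    e = r_plus / n_plus if n_plus > 0 else 0.0
    return dp, e, r, r_plus, n_plus


def evaluate_realization(
    roster: Roster, spec: PartitionSpec, realization: CVRealization
) -> tuple[float, float, int, int, int]:
    """Split -> fit -> score -> DP/E for one prepared realization."""
    scores = score_realization(roster, spec, realization)
    n_augmented = roster.n_candidates + len(realization.reserved_ids)
    return dp_and_e(scores, realization, baseline=1.0 / n_augmented)


def evaluate_partition(
    roster: Roster,
    spec: PartitionSpec,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    seed: int = 0,
) -> ValidationResult:
    """Average DP and E over independent cross-validation realizations.

    Realization seeds derive deterministically from the master seed, so
    the result is reproducible bit-for-bit.  Realizations whose learning
    sample makes prior elicitation infeasible are dropped and counted in
    ``n_failed``.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rows = []
    n_failed = 0
    for i in range(n_realizations):
        child = realization_seed(seed, i)
        realization = split_solved(roster, split_fraction, seed=child)
        try:
            dp, e, r, r_plus, n_plus = evaluate_realization(roster, spec, realization)
        except ElicitationError:
            n_failed += 1
            continue
        rows.append(
            {"seed": child, "R": r, "R_plus": r_plus, "N_plus": n_plus,
             "DP": dp, "E": e}
        )
    frame = pd.DataFrame(
        rows, columns=["seed", "R", "R_plus", "N_plus", "DP", "E"]
    )
    n_ok = len(frame)
    if n_ok == 0:
        mean_dp = mean_e = sd_dp = sd_e = float("nan")
    else:
        mean_dp = float(frame["DP"].mean())
        mean_e = float(frame["E"].mean())
        sd_dp = float(frame["DP"].std(ddof=1)) if n_ok > 1 else 0.0
        sd_e = float(frame["E"].std(ddof=1)) if n_ok > 1 else 0.0
    return ValidationResult(
        realizations=frame,
        mean_DP=mean_dp,
        mean_E=mean_e,
        sd_DP=sd_dp,
        sd_E=sd_e,
        n_ok=n_ok,
        n_failed=n_failed,
    )


def randomize_scores(
    roster: Roster, realization: CVRealization, seed: int = 0
) -> ScoreTable:
    """Null baseline: i.i.d. uniform scores over the augmented candidates.

    Each candidate of the augmented set receives an independent
    Uniform(0,1) draw, normalized to sum to 1.  Used only to calibrate
    DP/E against chance; carries no cell structure.
    """
    augmented = _augmented_roster(roster, realization)
    ids = sorted(r.victim_id for r in augmented.candidates)
    rng = np.random.default_rng(seed)
    raw = rng.uniform(size=len(ids))
    values = raw / raw.sum()
    frame = pd.DataFrame(
        {
            "victim_id": ids,
            "cell_id": pd.array([pd.NA] * len(ids), dtype="Int64"),
            "score": values,
        }
    ).sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    frame["block_rank"] = np.arange(1, len(frame) + 1)
    blocks = frame[["cell_id", "score", "block_rank"]].copy()
    blocks["n_members"] = 1
    return ScoreTable(scores=frame, unassignable_mass=0.0, block_ranking=blocks)


def evaluate_random_baseline(
    roster: Roster,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    seed: int = 0,
) -> ValidationResult:
    """DP/E of the random-score null over matched realizations.

    Uses the same split seeds as :func:`evaluate_partition` with the
    same master seed, so the comparison is paired realization by
    realization.
    """
    rows = []
    for i in range(n_realizations):
        child = realization_seed(seed, i)
        realization = split_solved(roster, split_fraction, seed=child)
        scores = randomize_scores(roster, realization, seed=child)
        n_augmented = roster.n_candidates + len(realization.reserved_ids)
        dp, e, r, r_plus, n_plus = dp_and_e(
            scores, realization, baseline=1.0 / n_augmented
        )
        rows.append(
            {"seed": child, "R": r, "R_plus": r_plus, "N_plus": n_plus,
             "DP": dp, "E": e}
        )
    frame = pd.DataFrame(rows)
    n_ok = len(frame)
    return ValidationResult(
        realizations=frame,
        mean_DP=float(frame["DP"].mean()),
        mean_E=float(frame["E"].mean()),
        sd_DP=float(frame["DP"].std(ddof=1)) if n_ok > 1 else 0.0,
        sd_E=float(frame["E"].std(ddof=1)) if n_ok > 1 else 0.0,
        n_ok=n_ok,
        n_failed=0,
    )


def _spec_for(
    subset: Sequence[str], window_days: Optional[int]
) -> PartitionSpec:
    return PartitionSpec(
        variables=tuple(subset),
        window_days=window_days if "temporal" in subset else None,
    )


def grid_search(
    roster: Roster,
    variable_subsets: Sequence[Sequence[str]],
    t_grid: Optional[Sequence[int]] = None,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every (variable subset, T) partition of the grid.

    T applies only to subsets containing the temporal variable; the
    default T grid is 1..90 days in steps of 3.  Duplicate grid entries
    are evaluated once.  All entries share the same master seed, hence
    the same split sequence, which pairs the comparison across models.

    Returns a table ``variables, T, mean_DP, mean_E, sd_DP, sd_E,
    n_ok, n_failed`` sorted by descending mean_DP then mean_E.
    """
    if t_grid is None:
        t_grid = DEFAULT_T_GRID
    combos = []
    seen = set()
    for subset in variable_subsets:
        subset = tuple(sorted(set(subset)))
        if not subset:
            continue
        windows = list(t_grid) if "temporal" in subset else [None]
        for t in windows:
            key = (subset, t)
            if key not in seen:
                seen.add(key)
                combos.append(key)
    if not combos:
        raise ValueError("grid is empty")

    rows = []
    for subset, t in combos:
        result = evaluate_partition(
            roster,
            _spec_for(subset, t),
            n_realizations=n_realizations,
            split_fraction=split_fraction,
            seed=seed,
        )
        rows.append(
            {
                "variables": "+".join(subset),
                "T": t if t is not None else pd.NA,
                "mean_DP": result.mean_DP,
                "mean_E": result.mean_E,
                "sd_DP": result.sd_DP,
                "sd_E": result.sd_E,
                "n_ok": result.n_ok,
                "n_failed": result.n_failed,
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["mean_DP", "mean_E"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return frame


def plot_grid_search(frame: pd.DataFrame, path) -> None:
    """Scatter mean_E (x) vs mean_DP (y), one point per grid entry."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, group in frame.groupby("variables"):
        ax.scatter(group["mean_E"], group["mean_DP"], label=name, s=25, alpha=0.8)
    ax.set_xlabel("Efficacy Rate  <E>")
    ax.set_ylabel("Discriminating Power  <DP>")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
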