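"""Dirichlet-multinomial core: prior elicitation, conjugate update, scores.

Model
-----
Let theta_j be the probability that the queried remains belong to cell j
of the partition (m cells).  The solved-case counts I = (I_1..I_m),
n_s = sum(I_j), are modelled as multinomial(n_s, theta), and theta gets a
Dirichlet(alpha_1..alpha_m) prior.  The prior is elicited from the
candidate counts alone:

* prior cell means must match the candidate shares, E(theta_j) = N_j / N,
  so that before any solved case every candidate is equally likely;
* the prior must stay vague, pinned down by requiring the coefficient of
  variation of the *most populated* cell (N_k = max_j N_j) to be 1.

Together these give the closed form

    alpha0 = N / N_k - 2,        alpha_j = (N_j / N) * alpha0,

and conjugacy makes the posterior Dirichlet with alpha'_j = alpha_j + I_j,
whose mean is thetahat_j = (alpha_j + I_j) / (alpha0 + n_s).

Every still-unidentified candidate of cell j then receives the same score
P_j^i = thetahat_j / N_j, the posterior probability that this particular
person corresponds to the remains.  Ranking candidates by decreasing
score yields a ranking of tied blocks (one block per cell).

The CV=1 constraint is infeasible when N_k >= N/2 (alpha0 <= 0); by
default this raises :class:`~dviprior.errors.ElicitationError`.  A caller
may instead relax the target coefficient of variation c: from the
Dirichlet moments, CV(theta_k)**2 = (N/N_k - 1)/(alpha0 + 1), so
alpha0 = (N/N_k - 1)/c**2 - 1, which reduces to the closed form above at
c = 1 and is feasible iff c**2 < N/N_k - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ElicitationError
from .partition import CellTable

_ATOL = 1e-12


@dataclass(frozen=True)
class DirichletParams:
    """Hyperparameter vector of a Dirichlet distribution over cells."""

    alpha: np.ndarray
    stage: str = "prior"

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        if alpha.ndim != 1 or alpha.size == 0:
            raise ValueError("alpha must be a non-empty vector")
        if (alpha < 0).any():
            raise ValueError("alpha entries must be non-negative")
        if alpha.sum() <= 0:
            raise ValueError("alpha0 must be positive")

    @property
    def alpha0(self) -> float:
        return float(self.alpha.sum())

    def mean(self) -> np.ndarray:
        return self.alpha / self.alpha0

    def variance(self) -> np.ndarray:
        a0 = self.alpha0
        return self.alpha * (a0 - self.alpha) / (a0**2 * (a0 + 1.0))


@dataclass(frozen=True)
class CellProbabilities:
    """Cell probability vector theta at the prior or posterior stage."""

    theta: np.ndarray
    stage: str

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if self.stage not in ("prior", "posterior"):
            raise ValueError(f"stage must be prior/posterior, got {self.stage!r}")
        if (theta < -_ATOL).any() or (theta > 1 + _ATOL).any():
            raise ValueError("theta entries must lie in [0, 1]")
        if abs(theta.sum() - 1.0) > 1e-9:
            raise ValueError(f"theta must sum to 1, got {theta.sum()!r}")


@dataclass(frozen=True)
class ScoreTable:
    """Per-victim scores and the induced block ranking.

    ``scores`` has one row per scored candidate with columns
    ``victim_id, cell_id, score, block_rank``; all members of a cell
    share one score and one block rank (rank 1 = highest score, ties
    between equal-score cells broken by ascending cell_id).

    ``unassignable_mass`` is the posterior probability of cells that
    still carry mass (I_j > 0 counted in the update) but hold no
    remaining candidate (N_j = 0); it is reported, never renormalized,
    so sum(scores) + unassignable_mass = 1.
    """

    scores: pd.DataFrame
    unassignable_mass: float
    block_ranking: pd.DataFrame

    @property
    def total_mass(self) -> float:
        return float(self.scores["score"].sum()) + self.unassignable_mass

    def write_csv(self, path: str | Path) -> None:
        self.scores.to_csv(path, index=False)


def elicit_prior(cell_table: CellTable, cv_target: float = 1.0) -> DirichletParams:
    """Closed-form Dirichlet prior from the candidate counts.

    Raises :class:`ElicitationError` when the constraint is infeasible,
    i.e. alpha0 = (N/N_k - 1)/cv_target**2 - 1 <= 0 (at the default
    target this is N_k >= N/2: the most populated cell holds at least
    half the candidates).  Cells with N_j = 0 get alpha_j = 0: nobody
    with that combination of variable values is missing, so the prior
    mass of the cell is null.  When a single cell holds every candidate
    the prior is the degenerate point mass on that cell and the CV
    condition is void.
    """
    n_j = np.asarray(cell_table.N_j, dtype=float)
    n_total = n_j.sum()
    if n_total < 1:
        raise ElicitationError(int(n_total), 0, cv_target)
    n_max = n_j.max()
    if (n_j > 0).sum() == 1:
        # all candidates in one cell: theta is the point mass there
        return DirichletParams(alpha=(n_j > 0).astype(float), stage="prior")
    alpha0 = (n_total / n_max - 1.0) / cv_target**2 - 1.0
    if alpha0 <= 0:
        raise ElicitationError(int(n_total), int(n_max), cv_target)
    return DirichletParams(alpha=n_j / n_total * alpha0, stage="prior")


def prior_probs(prior: DirichletParams, cell_table: CellTable) -> CellProbabilities:
    """Prior cell probabilities: theta_j = alpha_j/alpha0 = N_j/N."""
    return CellProbabilities(theta=prior.mean(), stage="prior")


def update_posterior(
    prior: DirichletParams, cell_table: CellTable
) -> tuple[DirichletParams, CellProbabilities]:
    """Conjugate update with the solved-case counts of the table.

    Returns the posterior Dirichlet (alpha'_j = alpha_j + I_j) and its
    mean thetahat_j = (alpha_j + I_j) / (alpha0 + n_s).
    """
    i_j = np.asarray(cell_table.I_j, dtype=float)
    if i_j.shape != prior.alpha.shape:
        raise ValueError(
            f"cell table has {i_j.size} cells but the prior has "
            f"{prior.alpha.size} hyperparameters"
        )
    posterior = DirichletParams(alpha=prior.alpha + i_j, stage="posterior")
    return posterior, CellProbabilities(theta=posterior.mean(), stage="posterior")


def victim_scores(
    theta_post: CellProbabilities, cell_table: CellTable
) -> ScoreTable:
    """Spread each cell's posterior mass uniformly over its candidates.

    Every candidate i of cell j scores P_j^i = thetahat_j / N_j.  Cells
    with no candidates contribute their mass to ``unassignable_mass``.
    """
    if theta_post.stage != "posterior":
        raise ValueError("victim_scores requires posterior probabilities")
    theta = theta_post.theta
    if theta.size != cell_table.m:
        raise ValueError("theta and cell table sizes differ")

    per_victim = np.zeros_like(theta)
    populated = cell_table.N_j > 0
    per_victim[populated] = theta[populated] / cell_table.N_j[populated]
    unassignable = float(theta[~populated].sum())

    blocks = pd.DataFrame(
        {
            "cell_id": np.arange(1, cell_table.m + 1)[populated],
            "score": per_victim[populated],
            "n_members": cell_table.N_j[populated],
        }
    ).sort_values(
        ["score", "cell_id"], ascending=[False, True], kind="mergesort"
    )
    blocks["block_rank"] = np.arange(1, len(blocks) + 1)
    blocks = blocks.reset_index(drop=True)

    rank_of_cell = dict(zip(blocks["cell_id"], blocks["block_rank"]))
    rows = []
    for j in np.flatnonzero(populated):
        cell_id = j + 1
        for vid in cell_table.member_ids[j]:
            rows.append(
                {
                    "victim_id": vid,
                    "cell_id": cell_id,
                    "score": per_victim[j],
                    "block_rank": rank_of_cell[cell_id],
                }
            )
    scores = pd.DataFrame(
        rows, columns=["victim_id", "cell_id", "score", "block_rank"]
    ).sort_values(["block_rank", "victim_id"], kind="mergesort").reset_index(drop=True)

    return ScoreTable(
        scores=scores, unassignable_mass=unassignable, block_ranking=blocks
    )


def fit_scores(cell_table: CellTable, cv_target: float = 1.0) -> ScoreTable:
    """Elicit, update and score in one call."""
    prior = elicit_prior(cell_table, cv_target=cv_target)
    _, theta_post = update_posterior(prior, cell_table)
    return victim_scores(theta_post, cell_table)


def summarize_cells(
    cell_table: CellTable,
    prior: Optional[DirichletParams] = None,
    cv_target: float = 1.0,
) -> pd.DataFrame:
    """Per-cell summary: counts, prior and posterior probabilities."""
    if prior is None:
        prior = elicit_prior(cell_table, cv_target=cv_target)
    _, theta_post = update_posterior(prior, cell_table)
    frame = cell_table.to_frame()
    frame["alpha_j"] = prior.alpha
    frame["theta_prior"] = prior.mean()
    frame["theta_post"] = theta_post.theta
    return frame
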