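"""Synthetic cohort generator with controllable cell concentration.

Real casework rosters for this class of events are not public, so every
other module is exercised on generated cohorts.  The generator emulates
the structure the model sees — candidates spread over geographic /
political categories and a backward time horizon, plus a set of solved
cases — and nothing more (no family structure, no spatial coordinates).

Candidates are drawn independently: kidnap day offsets uniform on
1..horizon_days before the event, categorical labels multinomial with
the configured weights.  Solved cases are drawn from a two-component
mixture controlled by ``concentration`` c >= 0: with probability
c / (1 + c) a solved case is placed in one of the designated *hot
cells* (chosen uniformly among them), otherwise its attributes are
drawn from the same background distribution as the candidates.  c = 0
therefore reproduces the null assumption that the solved cases are a
uniform random sample of the deaths; large c concentrates nearly all
solved-case mass in the hot cells.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import elicit_prior, update_posterior
from .errors import ConfigError
from .io import EventSpec, Roster, VictimRecord
from .partition import PartitionSpec, build_cell_table, temporal_bin


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    ``hot_cells`` entries are mappings with any of the keys
    ``geo_area``, ``political_group`` and ``day_range`` (an inclusive
    ``(low, high)`` pair of day offsets before the event); attributes a
    hot cell leaves unspecified are drawn from the background.
    """

    n_victims: int
    n_solved: int
    event_date: _dt.date
    geo_labels: tuple[str, ...] = ("geo1", "geo2", "geo3")
    political_labels: tuple[str, ...] = ()
    horizon_days: int = 45
    concentration: float = 0.0
    hot_cells: tuple[Mapping, ...] = ()
    seed: int = 0
    geo_weights: Optional[tuple[float, ...]] = None
    political_weights: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        object.__setattr__(self, "geo_labels", tuple(self.geo_labels))
        object.__setattr__(self, "political_labels", tuple(self.political_labels))
        object.__setattr__(self, "hot_cells", tuple(self.hot_cells))
        if self.n_victims < 1:
            raise ConfigError("n_victims must be >= 1")
        if not 0 <= self.n_solved <= self.n_victims:
            raise ConfigError("need 0 <= n_solved <= n_victims")
        if self.horizon_days < 1:
            raise ConfigError("horizon_days must be >= 1")
        if self.concentration < 0:
            raise ConfigError("concentration must be >= 0")
        if self.concentration > 0 and not self.hot_cells:
            raise ConfigError("concentration > 0 requires hot_cells")
        for cell in self.hot_cells:
            bad = set(cell) - {"geo_area", "political_group", "day_range"}
            if bad:
                raise ConfigError(f"unknown hot-cell keys: {sorted(bad)}")
            if "geo_area" in cell and cell["geo_area"] not in self.geo_labels:
                raise ConfigError(
                    f"hot cell references unknown geo label {cell['geo_area']!r}"
                )
            if (
                "political_group" in cell
                and cell["political_group"] not in self.political_labels
            ):
                raise ConfigError(
                    "hot cell references unknown political label "
                    f"{cell['political_group']!r}"
                )
            if "day_range" in cell:
                lo, hi = cell["day_range"]
                if not 1 <= lo <= hi <= self.horizon_days:
                    raise ConfigError(
                        f"hot-cell day_range {cell['day_range']} outside "
                        f"1..{self.horizon_days}"
                    )
        for weights, labels, name in (
            (self.geo_weights, self.geo_labels, "geo_weights"),
            (self.political_weights, self.political_labels, "political_weights"),
        ):
            if weights is not None:
                if len(weights) != len(labels):
                    raise ConfigError(f"{name} length does not match labels")
                if min(weights) < 0 or sum(weights) <= 0:
                    raise ConfigError(f"{name} must be non-negative, sum > 0")

    @property
    def hot_probability(self) -> float:
        """Mixture weight of the hot-cell component, c / (1 + c)."""
        return self.concentration / (1.0 + self.concentration)

    def _weights(self, which: str) -> Optional[np.ndarray]:
        w = self.geo_weights if which == "geo" else self.political_weights
        if w is None:
            return None
        w = np.asarray(w, dtype=float)
        return w / w.sum()


def _draw_background(config: SyntheticConfig, rng: np.random.Generator):
    day = int(rng.integers(1, config.horizon_days + 1))
    geo = str(rng.choice(config.geo_labels, p=config._weights("geo")))
    pol = (
        str(rng.choice(config.political_labels, p=config._weights("political")))
        if config.political_labels
        else None
    )
    return day, geo, pol


def _draw_hot(config: SyntheticConfig, rng: np.random.Generator):
    cell = config.hot_cells[int(rng.integers(len(config.hot_cells)))]
    day, geo, pol = _draw_background(config, rng)
    if "day_range" in cell:
        lo, hi = cell["day_range"]
        day = int(rng.integers(lo, hi + 1))
    if "geo_area" in cell:
        geo = cell["geo_area"]
    if "political_group" in cell:
        pol = cell["political_group"]
    return day, geo, pol


def generate_roster(config: SyntheticConfig) -> Roster:
    """Generate a seeded synthetic roster.

    Returns a roster with ``n_victims`` candidates and ``n_solved``
    identified cases; identical configs give identical rosters.
    """
    rng = np.random.default_rng(config.seed)
    event = EventSpec(
        event_id="synthetic",
        event_date=config.event_date,
        n_e=config.n_victims + config.n_solved,
        description="synthetic cohort",
    )
    records = []
    for i in range(config.n_victims):
        day, geo, pol = _draw_background(config, rng)
        records.append(
            VictimRecord(
                victim_id=f"c{i + 1:05d}",
                kidnap_date=config.event_date - _dt.timedelta(days=day),
                geo_area=geo,
                political_group=pol if pol is not None else "UNKNOWN",
                status="candidate",
            )
        )
    p_hot = config.hot_probability
    for i in range(config.n_solved):
        if p_hot > 0 and rng.uniform() < p_hot:
            day, geo, pol = _draw_hot(config, rng)
        else:
            day, geo, pol = _draw_background(config, rng)
        records.append(
            VictimRecord(
                victim_id=f"s{i + 1:05d}",
                kidnap_date=config.event_date - _dt.timedelta(days=day),
                geo_area=geo,
                political_group=pol if pol is not None else "UNKNOWN",
                status="identified",
            )
        )
    return Roster.from_records(event, records)


def default_partition_spec(config: SyntheticConfig, window_days: int = 15) -> PartitionSpec:
    """Declared grid covering the whole generated cohort."""
    variables = ["temporal", "geographic"]
    if config.political_labels:
        variables.append("political")
    n_bins = (config.horizon_days - 1) // window_days + 1
    return PartitionSpec(
        variables=tuple(variables),
        window_days=window_days,
        geo_categories=config.geo_labels,
        political_categories=config.political_labels,
        n_temporal_bins=n_bins,
    )


def solved_cell_distribution(
    config: SyntheticConfig, spec: PartitionSpec
) -> dict[tuple, float]:
    """Exact cell distribution the solved cases are drawn from.

    Enumerates the discrete attribute space (day offset x geo x
    political) under the background and hot-cell mixture and folds it
    onto the cells of ``spec``.  Serves as the ground truth for
    parameter-recovery checks.
    """
    geo_w = config._weights("geo")
    if geo_w is None:
        geo_w = np.full(len(config.geo_labels), 1.0 / len(config.geo_labels))
    if config.political_labels:
        pol_labels: tuple = config.political_labels
        pol_w = config._weights("political")
        if pol_w is None:
            pol_w = np.full(len(pol_labels), 1.0 / len(pol_labels))
    else:
        pol_labels = (None,)
        pol_w = np.array([1.0])

    def accumulate(dist: dict, day_lo, day_hi, geo_fixed, pol_fixed, mass):
        n_days = day_hi - day_lo + 1
        for day in range(day_lo, day_hi + 1):
            rec_bin = None
            if "temporal" in spec.variables:
                date = config.event_date - _dt.timedelta(days=day)
                rec_bin = temporal_bin(date, config.event_date, spec.window_days)
            geo_iter = (
                [(geo_fixed, 1.0)]
                if geo_fixed is not None
                else list(zip(config.geo_labels, geo_w))
            )
            pol_iter = (
                [(pol_fixed, 1.0)]
                if pol_fixed is not None or not config.political_labels
                else list(zip(pol_labels, pol_w))
            )
            for geo, gw in geo_iter:
                for pol, pw in pol_iter:
                    parts = []
                    for var in spec.active:
                        if var == "temporal":
                            parts.append(rec_bin)
                        elif var == "political":
                            parts.append(pol if pol is not None else "UNKNOWN")
                        else:
                            parts.append(geo)
                    label = tuple(parts)
                    dist[label] = dist.get(label, 0.0) + mass * gw * pw / n_days

    dist: dict[tuple, float] = {}
    p_hot = config.hot_probability
    accumulate(dist, 1, config.horizon_days, None, None, 1.0 - p_hot)
    if p_hot > 0:
        share = p_hot / len(config.hot_cells)
        for cell in config.hot_cells:
            lo, hi = cell.get("day_range", (1, config.horizon_days))
            accumulate(
                dist,
                lo,
                hi,
                cell.get("geo_area"),
                cell.get("political_group"),
                share,
            )
    return dist


def recover_parameters(
    config: SyntheticConfig,
    spec: PartitionSpec,
    n_solved_values: Optional[Sequence[int]] = None,
    n_reps: int = 1,
) -> pd.DataFrame:
    """Posterior recovery of the generating solved-case distribution.

    For each requested number of solved cases, generates ``n_reps``
    fresh cohorts, fits the posterior, and reports the RMSE between the
    posterior cell probabilities and the exact mixture distribution the
    solved cases were drawn from.  As the solved sample grows the
    posterior mean converges to that distribution, so the RMSE should
    fall.

    Returns a frame with columns ``n_solved, rep, seed, rmse``.
    """
    if n_solved_values is None:
        n_solved_values = [config.n_solved]
    truth = solved_cell_distribution(config, spec)
    rows = []
    for si, n_solved in enumerate(n_solved_values):
        for rep in range(n_reps):
            seed = int(
                np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(si, rep)
                ).generate_state(1)[0]
                % (2**31)
            )
            cfg = SyntheticConfig(
                n_victims=config.n_victims,
                n_solved=int(n_solved),
                event_date=config.event_date,
                geo_labels=config.geo_labels,
                political_labels=config.political_labels,
                horizon_days=config.horizon_days,
                concentration=config.concentration,
                hot_cells=config.hot_cells,
                seed=seed,
                geo_weights=config.geo_weights,
                political_weights=config.political_weights,
            )
            roster = generate_roster(cfg)
            table = build_cell_table(roster, spec)
            prior = elicit_prior(table)
            _, theta_post = update_posterior(prior, table)
            est = dict(zip(table.labels, theta_post.theta))
            cells = set(truth) | set(est)
            sq = [
                (est.get(c, 0.0) - truth.get(c, 0.0)) ** 2 for c in cells
            ]
            rows.append(
                {
                    "n_solved": int(n_solved),
                    "rep": rep,
                    "seed": seed,
                    "rmse": float(np.sqrt(np.mean(sq))),
                }
            )
    return pd.DataFrame(rows)
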