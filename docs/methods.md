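# Methods

## Problem

After a well-delimited mass-fatality event (known date `T_e` and death
toll `n_e`), investigators hold two lists: the candidate victims — people
reported kidnapped or missing before `T_e` who could correspond to
remains recovered from the event — and the unidentified human remains
themselves.  A subset of cases has already been identified.  When the
solved cases show a pattern in non-genetic variables (where and when
people were taken, political affiliation), that pattern can be learned
and used to rank the remaining candidates for a new set of remains,
directing scarce resources (family reference DNA sampling, archival
work) toward the most plausible matches.  `dviprior` implements this
prioritization engine together with the cross-validation machinery used
to choose which variables, and which partition of them, to learn from.

## Model

The non-genetic variable space is cut into `m` cells: backward temporal
windows of `T` days from the event date, crossed with geographic areas
and/or political groups.  Cell `j` holds `N_j` still-unidentified
candidates (`sum N_j = N`) and `I_j` solved cases (`sum I_j = n_s`).

Let `theta_j` be the probability that the queried remains belong to
someone from cell `j`.  The solved-case counts are modelled as
multinomial(`n_s`, `theta`), and `theta` receives a Dirichlet prior with
hyperparameters `alpha_j` elicited from the candidate counts alone:

* **Prior means match candidate shares.**  `E(theta_j) = alpha_j/alpha0
  = N_j/N`, so that before any solved case is observed every candidate
  is equally likely (a cell is exactly as probable as it is populated).
* **The prior stays vague.**  The means leave `alpha0 = sum alpha_j`
  free; it is pinned by requiring the coefficient of variation of the
  most populated cell (`N_k = max N_j`) to be 1, which makes every other
  cell's CV larger.  Solving the Dirichlet moment equations gives the
  closed form

      alpha0 = N/N_k - 2,      alpha_j = (N_j/N) * alpha0.

  A cell with no candidates gets `alpha_j = 0` and prior (and posterior
  prior-component) mass zero: nobody with that combination of values is
  missing.

Conjugacy gives the posterior Dirichlet with `alpha'_j = alpha_j + I_j`
and posterior mean

    thetahat_j = (alpha_j + I_j) / (alpha0 + n_s).

Every candidate of cell `j` then scores `P_j^i = thetahat_j / N_j`, the
posterior probability that this particular person is the match; members
of one cell are exchangeable, so the ranking is a ranking of tied
blocks, sorted by decreasing per-victim score with ties between blocks
broken by ascending cell id.

### Degenerate and infeasible cases

* The CV=1 constraint is infeasible when `N_k >= N/2` (`alpha0 <= 0`).
  This is raised as an error rather than silently clamped — note it
  always happens with `m = 2` cells, by pigeonhole.  A caller may relax
  the target CV to some `c`; the moment equations give
  `CV(theta_k)^2 = (N/N_k - 1)/(alpha0 + 1)`, hence
  `alpha0 = (N/N_k - 1)/c^2 - 1`, which reduces to the standard form at
  `c = 1` and is feasible iff `c^2 < N/N_k - 1`.
* When one single cell holds every candidate (including `m = 1`) the
  prior on `theta` is the point mass on that cell; no `alpha0` can
  satisfy any CV condition and none is needed.
* A cell may carry posterior mass but no remaining candidate (all its
  members already identified).  That mass is reported as *unassignable*
  rather than renormalized, so `sum of scores + unassignable mass = 1`
  holds exactly and scores keep their literal probability meaning.

## Cross-validation model selection

Each partition of the variable space (choice of variable subset, and of
`T` for temporal partitions) is a model.  One *realization* splits the
solved cases at random into a learning sample (75% by default; size
`round(0.75 * n_s)` with round-half-to-even) and a reserved sample.  The
reserved cases are pretended unidentified — they re-enter the candidate
set, growing it to `N' = N + R` — the model is fitted on the learning
sample only, and all `N'` candidates are scored.  Against the uniform
baseline `1/N'`:

* **Discriminating Power** `DP = R+/R`: fraction of reserved cases
  scoring strictly above baseline (ties do not count);
* **Efficacy Rate** `E = R+/N+`: reserved improvers relative to all
  improvers (`E = 0` when nothing improves).

Averages over realizations (50 by default) give `<DP>` and `<E>` per
model; the grid search scans variable subsets crossed with `T` from 1 to
90 days in steps of 3 and sorts by `<DP>`, then `<E>`.  Realization
seeds derive deterministically from one master seed
(`SeedSequence(master, spawn_key=(i,))`), and every grid entry reuses
the same master seed so models are compared on identical split
sequences.  Realizations whose learning configuration makes elicitation
infeasible are dropped and counted, never imputed.  A null reference is
provided by assigning candidates i.i.d. uniform scores normalized to
sum 1.

## Synthetic cohorts

No casework roster of this kind is public, so the package ships a
generator that emulates exactly what the model sees.  Candidates draw a
kidnap day uniformly over a horizon (default 45 days — three 15-day
windows) and categorical labels multinomially (default three geographic
areas, mirroring the scale of the worked nine-cell example).  Solved
cases come from a two-component mixture governed by `concentration`
`c >= 0`: with probability `c/(1+c)` the case is placed in a designated
*hot cell*, otherwise it is a background draw.  `c = 0` reproduces the
assumption that solved cases are a uniform random sample of the deaths;
large `c` concentrates nearly all solved mass in the hot cells.  The
generating solved-case cell distribution is available in closed form
(by enumerating the discrete attribute space), which the
parameter-recovery report uses as ground truth for the RMSE of the
posterior.

What the generator does **not** emulate: family structure, reporting
bias, spatially continuous locations, detention-circuit dynamics, or
correlation between a person's attributes and their chance of being
identified.  Tests passing on these cohorts show that the machinery is
correct under the model's own assumptions, not that real casework
satisfies those assumptions.

## Numerical and design choices

* Temporal bins are half-open, day-granular, backward from `T_e`: the
  day immediately before the event is in bin 1, bin `b` covers offsets
  `(b-1)T + 1 .. bT`.  Half-open intervals prevent double counting; no
  boundary convention changes the worked example, whose members are
  spread across their windows.
* Records kidnapped on or after `T_e` are excluded from the candidate
  set (strict inequality); identified cases dated on/after `T_e` are
  rejected outright as inconsistent with the event delimitation.
* Missing geographic/political values map to a reserved `UNKNOWN`
  category forming its own cells; dropping such rows would silently
  break the normalization of `theta` over the candidate set.
* Cell numbering is row-major with the geographic axis fastest and the
  temporal axis slowest; declared category lists freeze the grid shape
  (empty cells retained) so it is stable across realizations, while
  undeclared grids keep only occupied cells.
* With no solved cases every score is exactly `1/N`, the uniform
  initial instance of knowledge.
* All probabilities are carried in full precision; 3-decimal rounding
  is display-only.

Default problem sizes in the test-suite simulations (cohorts of a few
hundred candidates, tens of solved cases, 25–100 repetitions per
condition) were chosen to mirror the scale of the worked example while
keeping the full suite fast to run routinely.

## Known limitations

* Scores condition on the solved cases being a random sample of the
  deaths (assumption of the model).  Identification effort is rarely
  random in practice; the cross-validation metrics are the guard
  against learning an artifact of that bias, not a cure for it.
* Under a truly patternless cohort the model's mean DP sits slightly
  *below* the random-score null rather than exactly at it — a lattice
  effect: a cell beats the baseline only when its integer learning
  count strictly exceeds `n_L * N_j/N'`, and for skewed binomial counts
  that event has probability a little under one half.  The method is
  thus mildly conservative under the null; it does not fabricate
  patterns.
* Posterior summaries are means only; no credible intervals or full
  posterior sampling are exposed.
* Partitions are explicit grids; no data-driven pooling or clustering
  of sparse cells is attempted.
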