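"""Low-ITH prognostic signature construction and evaluation.

A prognostic gene signature built from single-region cohorts is only as
portable as its genes are stable across regions of a tumor. The pipeline
here therefore restricts candidates to low-ITH genes (IHS < 0.25) before
any survival modelling, then:

1. screens genes by univariate Cox regression in every training cohort,
   keeping genes significant (p < 0.05) with a consistent hazard
   direction in all of them (protective HR < 1, risk HR > 1);
2. keeps genes whose association is stable under patient-level bootstrap
   resampling (pass in >= ``pass_fraction`` of ``n_boot`` iterations);
3. ranks the stable genes by permutation variable importance in random
   survival forests and picks the nested top-j subset with the best mean
   out-of-bag concordance;
4. turns the chosen genes into a risk score — by default the multivariate
   Cox linear predictor ``sum_g w_g * z(expr_g)`` on pooled z-scored
   training data (portable and auditable; a forest-based rule is
   pluggable).

Evaluation covers both jobs of such a signature: prognostic power
(median-split hazard ratio, log-rank test, IPCW time-dependent AUC) and
ITH robustness on multi-region data (median signature-gene IHS,
discordant-tumor proportion under a median split, and the PGOR curve AUC
of clustering samples on the signature sub-matrix).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

from .diversity import concordance_classify
from .ihs import auc_pgor, pgor_curve

__all__ = [
    "SurvivalCohort",
    "SignatureModel",
    "filter_low_ith",
    "univariate_cox_table",
    "cox_screen",
    "CoxScreenResult",
    "bootstrap_stability",
    "forest_combination_search",
    "ForestSearchResult",
    "fit_signature_weights",
    "score",
    "evaluate_prognosis",
    "evaluate_ith_robustness",
    "ITHRobustnessResult",
    "LowITHSignatureModel",
    "SignatureResults",
]

_YEARS = {"days": 365.25, "months": 12.0, "years": 1.0}


@dataclass
class SurvivalCohort:
    """One survival cohort: per-patient expression, follow-up time and event.

    ``expression`` is genes x patients; ``time`` (> 0) and ``event``
    (0/1) are indexed by patient id. ``time_unit`` declares the scale so
    evaluation grids can be expressed in years.
    """

    name: str
    expression: pd.DataFrame = field(repr=False)
    time: pd.Series = field(repr=False)
    event: pd.Series = field(repr=False)
    time_unit: str = "months"

    def __post_init__(self):
        patients = list(self.expression.columns)
        self.time = self.time.loc[patients].astype(float)
        self.event = self.event.loc[patients].astype(int)
        if (self.time <= 0).any():
            raise ValueError(f"cohort {self.name}: non-positive follow-up times")
        if not set(self.event.unique()) <= {0, 1}:
            raise ValueError(f"cohort {self.name}: events must be 0/1")
        if self.time_unit not in _YEARS:
            raise ValueError(f"unknown time_unit {self.time_unit!r}")

    @property
    def n_patients(self) -> int:
        return self.expression.shape[1]

    def zscored(self, genes=None) -> pd.DataFrame:
        """Per-gene z-scores across this cohort's patients (patients x genes)."""
        sub = self.expression if genes is None else self.expression.loc[list(genes)]
        mat = sub.T
        sd = mat.std(ddof=0).replace(0.0, np.nan)
        return (mat - mat.mean()) / sd


def filter_low_ith(ihs_values, threshold: float = 0.25) -> list[str]:
    """Genes with IHS strictly below the threshold (candidate pool)."""
    if isinstance(ihs_values, pd.DataFrame):
        ihs_values = ihs_values["IHS"]
    kept = list(ihs_values.index[ihs_values < threshold])
    if not kept:
        raise ValueError(
            f"no gene has IHS < {threshold}; relax the threshold or check inputs"
        )
    return kept


# ---------------------------------------------------------------------------
# univariate Cox machinery


def _cox_score_test(X: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Vectorized univariate Cox score test per column of X (Breslow ties).

    Returns (beta_one_step, chi2, p): the efficient score U and information
    V over the risk sets give a one-step estimate U/V and the score
    statistic U^2/V — the standard screening approximation for large gene
    panels.
    """
    from scipy import stats as sps

    order = np.argsort(-time, kind="mergesort")
    Xo, to, eo = X[order], time[order], event[order]
    n, G = Xo.shape
    S0 = 0.0
    S1 = np.zeros(G)
    S2 = np.zeros(G)
    U = np.zeros(G)
    V = np.zeros(G)
    i = 0
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        block = slice(i, j)
        S0 += j - i
        S1 += Xo[block].sum(axis=0)
        S2 += (Xo[block] ** 2).sum(axis=0)
        deaths = eo[block] == 1
        d = int(deaths.sum())
        if d:
            mean = S1 / S0
            U += Xo[block][deaths].sum(axis=0) - d * mean
            V += d * (S2 / S0 - mean**2)
        i = j
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(V > 0, U / V, np.nan)
        chi2 = np.where(V > 0, U**2 / V, np.nan)
    p = sps.chi2.sf(chi2, df=1)
    return beta, chi2, p


def univariate_cox_table(
    cohort: SurvivalCohort, genes, method: str = "full"
) -> pd.DataFrame:
    """Per-gene univariate Cox results (HR, p) on z-scored expression.

    ``method="full"`` fits each gene with lifelines (partial-likelihood
    estimates); ``method="score"`` uses the vectorized score test with a
    one-step HR — orders of magnitude faster for wide panels, standard for
    screening. Constant or non-convergent genes are flagged non-estimable.
    """
    Z = cohort.zscored(genes)
    rows = []
    if method == "score":
        valid = [g for g in Z.columns if Z[g].notna().all()]
        X = Z[valid].to_numpy()
        beta, _, p = _cox_score_test(X, cohort.time.to_numpy(), cohort.event.to_numpy())
        est = dict(zip(valid, zip(np.exp(beta), p)))
        for g in Z.columns:
            if g in est and np.isfinite(est[g][1]):
                rows.append((g, float(est[g][0]), float(est[g][1]), True))
            else:
                rows.append((g, np.nan, np.nan, False))
    elif method == "full":
        for g in Z.columns:
            x = Z[g]
            if x.isna().any():
                rows.append((g, np.nan, np.nan, False))
                continue
            df = pd.DataFrame({"time": cohort.time, "event": cohort.event, "x": x})
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph = CoxPHFitter()
                    cph.fit(df, duration_col="time", event_col="event")
                rows.append(
                    (g, float(np.exp(cph.params_["x"])), float(cph.summary.loc["x", "p"]), True)
                )
            except Exception:
                rows.append((g, np.nan, np.nan, False))
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows, columns=["gene", "HR", "p", "estimable"]).set_index("gene")


@dataclass
class CoxScreenResult:
    """Per-gene, per-cohort univariate Cox results and the intersected sets."""

    table: pd.DataFrame = field(repr=False)  # (gene, cohort) rows
    protective: list[str] = field(default_factory=list)
    risk: list[str] = field(default_factory=list)

    @property
    def passed(self) -> list[str]:
        return sorted(self.protective) + sorted(self.risk)


def cox_screen(
    cohorts: list[SurvivalCohort],
    genes,
    alpha: float = 0.05,
    method: str = "full",
) -> CoxScreenResult:
    """Multi-cohort univariate Cox screen with direction intersection.

    A gene passes when p < ``alpha`` in EVERY cohort with the same hazard
    direction; protective (HR < 1) and risk (HR > 1) sets are returned
    separately. Non-estimable genes are excluded and flagged in the table.
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    pieces = []
    for c in cohorts:
        t = univariate_cox_table(c, genes, method=method)
        t["cohort"] = c.name
        pieces.append(t.reset_index())
    table = pd.concat(pieces, ignore_index=True).set_index(["gene", "cohort"])
    protective, risk = [], []
    for g in genes:
        sub = table.xs(g, level="gene")
        if not sub["estimable"].all():
            continue
        if (sub["p"] < alpha).all():
            if (sub["HR"] < 1).all():
                protective.append(g)
            elif (sub["HR"] > 1).all():
                risk.append(g)
    return CoxScreenResult(table=table, protective=protective, risk=risk)


def bootstrap_stability(
    cohorts: list[SurvivalCohort],
    genes,
    directions: dict[str, int] | None = None,
    n_boot: int = 2500,
    pass_fraction: float = 0.8,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "score",
):
    """Bootstrap stability screen: keep genes that stay significant.

    Per iteration, patients are resampled with replacement within each
    cohort; a gene passes the iteration when its univariate Cox p < alpha
    in every cohort with its reference direction (from ``directions``,
    +1 risk / -1 protective; estimated from the full data when omitted).
    Genes with pass count >= ``pass_fraction * n_boot`` are kept.

    Returns ``(stable_genes, pass_counts)``.
    """
    genes = list(genes)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if directions is None:
        directions = {}
        for g in genes:
            hrs = []
            for c in cohorts:
                t = univariate_cox_table(c, [g], method=method)
                hrs.append(t.loc[g, "HR"])
            directions[g] = 1 if np.nanmean(np.log(hrs)) > 0 else -1
    rng = np.random.default_rng(seed)
    counts = pd.Series(0, index=genes, dtype=int)
    for _ in range(n_boot):
        ok = pd.Series(True, index=genes)
        for c in cohorts:
            idx = rng.integers(0, c.n_patients, size=c.n_patients)
            patients = c.expression.columns[idx]
            Z = c.zscored(genes).iloc[idx]
            valid = [g for g in genes if Z[g].notna().all()]
            time = c.time.loc[patients].to_numpy()
            event = c.event.loc[patients].to_numpy()
            if not valid or event.sum() == 0:
                ok[:] = False
                break
            beta, _, p = _cox_score_test(Z[valid].to_numpy(), time, event)
            res = pd.DataFrame({"beta": beta, "p": p}, index=valid)
            for g in genes:
                if g not in res.index:
                    ok[g] = False
                    continue
                b, pv = res.loc[g, "beta"], res.loc[g, "p"]
                if not (np.isfinite(pv) and pv < alpha and np.sign(b) == directions[g]):
                    ok[g] = False
        counts[ok] += 1
    stable = list(counts.index[counts >= pass_fraction * n_boot])
    return stable, counts


# ---------------------------------------------------------------------------
# random-survival-forest combination search


def _pooled_training_data(cohorts, genes):
    zs, times, events = [], [], []
    for c in cohorts:
        Z = c.zscored(genes)
        zs.append(Z)
        times.append(c.time)
        events.append(c.event)
    X = pd.concat(zs).fillna(0.0)
    time = pd.concat(times).to_numpy()
    event = pd.concat(events).to_numpy().astype(bool)
    return X, time, event


@dataclass
class ForestSearchResult:
    genes: list[str]
    importance: pd.Series = field(repr=False)
    subset_scores: pd.Series = field(repr=False)  # index: subset size j
    best_concordance: float = float("nan")
    low_confidence: bool = False


def forest_combination_search(
    cohorts: list[SurvivalCohort],
    stable_genes,
    n_replicates: int = 10,
    n_trees: int = 200,
    max_subset: int = 25,
    importance_repeats: int = 3,
    min_events: int = 10,
    seed: int = 0,
) -> ForestSearchResult:
    """Pick the best gene combination via random survival forests.

    Genes are ranked by permutation variable importance (drop in training
    concordance when a gene's column is shuffled) averaged over
    ``n_replicates`` forests; nested top-j subsets (j = 2..min(max_subset,
    #genes)) are then compared by out-of-bag concordance averaged over the
    replicates, and the best subset wins (ties -> smaller subset). A best
    concordance below 0.55 flags the result as low-confidence.
    """
    from sksurv.ensemble import RandomSurvivalForest
    from sksurv.util import Surv

    stable_genes = list(stable_genes)
    if len(stable_genes) < 2:
        raise ValueError("need at least 2 stable genes to search combinations")
    X, time, event = _pooled_training_data(cohorts, stable_genes)
    if event.sum() < min_events:
        raise ValueError(f"only {int(event.sum())} events in pooled training data")
    y = Surv.from_arrays(event=event, time=time)
    rng = np.random.default_rng(seed)

    imp = np.zeros(len(stable_genes))
    for rep in range(n_replicates):
        rsf = RandomSurvivalForest(
            n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
        )
        rsf.fit(X.to_numpy(), y)
        base = rsf.score(X.to_numpy(), y)
        for gi in range(len(stable_genes)):
            drops = []
            for _ in range(importance_repeats):
                Xp = X.to_numpy().copy()
                Xp[:, gi] = rng.permutation(Xp[:, gi])
                drops.append(base - rsf.score(Xp, y))
            imp[gi] += float(np.mean(drops))
    importance = pd.Series(imp / n_replicates, index=stable_genes).sort_values(
        ascending=False, kind="mergesort"
    )

    sizes = range(2, min(max_subset, len(stable_genes)) + 1)
    scores = {}
    for j in sizes:
        top = list(importance.index[:j])
        oobs = []
        for rep in range(n_replicates):
            rsf = RandomSurvivalForest(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                oob_score=True,
                n_jobs=1,
            )
            rsf.fit(X[top].to_numpy(), y)
            oobs.append(rsf.oob_score_)
        scores[j] = float(np.mean(oobs))
    subset_scores = pd.Series(scores)
    best_j = int(subset_scores.idxmax())  # first (smallest) argmax wins ties
    best = float(subset_scores.max())
    return ForestSearchResult(
        genes=list(importance.index[:best_j]),
        importance=importance,
        subset_scores=subset_scores,
        best_concordance=best,
        low_confidence=best < 0.55,
    )


# ---------------------------------------------------------------------------
# the signature object and scoring


@dataclass
class SignatureModel:
    """A fitted signature: ordered genes, weights, and the score rule."""

    genes: list[str]
    weights: dict[str, float]
    directions: dict[str, str]
    score_rule: str = "cox_linear_predictor"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for g in self.genes:
            d = self.directions.get(g)
            w = self.weights.get(g)
            if w is None or d is None:
                raise ValueError(f"gene {g} lacks weight or direction")
            if (w > 0 and d == "protective") or (w < 0 and d == "risk"):
                raise ValueError(f"gene {g}: weight sign inconsistent with direction {d}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        return cls(**json.loads(Path(path).read_text()))


def fit_signature_weights(
    cohorts: list[SurvivalCohort], genes, penalizer: float = 0.1
) -> dict[str, float]:
    """Multivariate Cox coefficients of the final genes on pooled z-scores."""
    X, time, event = _pooled_training_data(cohorts, genes)
    df = X.copy()
    df["time"], df["event"] = time, event.astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph = CoxPHFitter(penalizer=penalizer)
        cph.fit(df, duration_col="time", event_col="event")
    return {g: float(cph.params_[g]) for g in genes}


def score(model: SignatureModel, expression: pd.DataFrame) -> pd.Series:
    """Risk score per column of ``expression``: sum_g w_g * z(expr_g).

    z-scores are taken across the provided samples (the evaluation
    cohort), per the portable linear-predictor score rule. All model genes
    must be present.
    """
    missing = [g for g in model.genes if g not in expression.index]
    if missing:
        raise ValueError(f"expression matrix lacks signature genes: {missing}")
    sub = expression.loc[model.genes].T
    sd = sub.std(ddof=0).replace(0.0, 1.0)
    z = (sub - sub.mean()) / sd
    w = np.array([model.weights[g] for g in model.genes])
    return pd.Series(z.to_numpy() @ w, index=sub.index, name="risk_score")


def evaluate_prognosis(
    model: SignatureModel,
    cohorts: list[SurvivalCohort],
    eval_years=(1, 2, 3, 4, 5),
) -> pd.DataFrame:
    """Per-cohort prognostic performance of the signature.

    Median-split hazard ratio (high vs low risk) with 95% CI, log-rank p,
    and IPCW cumulative/dynamic time-dependent AUC on a yearly grid
    (clipped to each cohort's follow-up range), plus its mean.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    rows = []
    for c in cohorts:
        if c.event.sum() < 10:
            warnings.warn(f"cohort {c.name}: fewer than 10 events; unstable estimates")
        s = score(model, c.expression)
        high = (s > s.median()).astype(int)
        df = pd.DataFrame({"time": c.time, "event": c.event, "high": high})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
        ci = np.exp(cph.confidence_intervals_.loc["high"]).to_numpy()
        lr = logrank_test(
            c.time[high == 1], c.time[high == 0], c.event[high == 1], c.event[high == 0]
        )
        y = Surv.from_arrays(event=c.event.astype(bool), time=c.time)
        grid = np.array(eval_years, dtype=float) * _YEARS[c.time_unit]
        tmin, tmax = c.time.min(), c.time.max()
        grid = grid[(grid > tmin) & (grid < tmax)]
        if len(grid):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aucs, mean_auc = cumulative_dynamic_auc(y, y, s.to_numpy(), grid)
            mean_auc = float(mean_auc)
        else:
            aucs, mean_auc = np.array([]), float("nan")
        rows.append(
            {
                "cohort": c.name,
                "n": c.n_patients,
                "events": int(c.event.sum()),
                "hr_high_vs_low": hr,
                "hr_ci_low": float(ci[0]),
                "hr_ci_high": float(ci[1]),
                "logrank_p": float(lr.p_value),
                "mean_auc": mean_auc,
                "n_auc_times": len(grid),
            }
        )
    return pd.DataFrame(rows).set_index("cohort")


@dataclass
class ITHRobustnessResult:
    median_signature_ihs: float
    discordant_proportion: float
    tumor_labels: pd.Series = field(repr=False)
    pgor: np.ndarray = field(repr=False)
    pgor_auc: float = float("nan")
    n_patients: int = 0


def evaluate_ith_robustness(
    model: SignatureModel,
    expression: pd.DataFrame,
    patients: pd.Series,
    ihs_values,
    linkage: str = "complete",
) -> ITHRobustnessResult:
    """The three ITH-robustness metrics of a signature on multi-region data.

    (a) median IHS over the signature genes; (b) per-region risk scores
    split at the cohort median, per-tumor concordant-low / concordant-high
    / discordant labels and the discordant fraction; (c) the PGOR curve
    from clustering samples on the z-scored signature sub-matrix and its
    trapezoidal AUC (P - 1 for a perfectly concordant signature).
    """
    if isinstance(ihs_values, pd.DataFrame):
        ihs_values = ihs_values["IHS"]
    present = [g for g in model.genes if g in expression.index]
    absent = [g for g in model.genes if g not in expression.index]
    if absent:
        warnings.warn(f"signature genes missing from multi-region matrix: {absent}")
    if len(present) < 2:
        raise ValueError("fewer than 2 signature genes present in the matrix")
    in_table = [g for g in model.genes if g in ihs_values.index]
    median_ihs = float(ihs_values.loc[in_table].median()) if in_table else float("nan")

    eval_model = SignatureModel(
        genes=present,
        weights={g: model.weights[g] for g in present},
        directions={g: model.directions[g] for g in present},
        score_rule=model.score_rule,
        training_meta=model.training_meta,
    )
    s = score(eval_model, expression)
    labels, prop = concordance_classify(s, patients)

    sub = np.log2(expression.loc[present] + 1.0) if (expression.loc[present].to_numpy() >= 0).all() else expression.loc[present]
    pats = patients.loc[sub.columns]
    curve = pgor_curve(sub.T, pats.to_numpy(), linkage=linkage, zscore=True)
    return ITHRobustnessResult(
        median_signature_ihs=median_ihs,
        discordant_proportion=prop,
        tumor_labels=labels,
        pgor=curve,
        pgor_auc=auc_pgor(curve),
        n_patients=len(curve),
    )


# ---------------------------------------------------------------------------
# end-to-end model / results


@dataclass
class LowITHSignatureModel:
    """End-to-end builder: IHS filter -> Cox screen -> bootstrap -> forest.

    Thresholds and sizes default to the full-scale pipeline
    (n_boot = 2500 with an 80% pass threshold, 25-gene search cap); scale
    them down for desk-size experiments.
    """

    train_cohorts: list[SurvivalCohort]
    ihs_values: pd.Series | pd.DataFrame = field(repr=False)
    ihs_threshold: float = 0.25
    alpha: float = 0.05
    n_boot: int = 2500
    pass_fraction: float = 0.8
    n_replicates: int = 10
    n_trees: int = 200
    max_subset: int = 25
    screen_method: str = "full"
    bootstrap_method: str = "score"

    def fit(self, seed: int = 0) -> "SignatureResults":
        candidates = filter_low_ith(self.ihs_values, self.ihs_threshold)
        candidates = [
            g for g in candidates
            if all(g in c.expression.index for c in self.train_cohorts)
        ]
        if not candidates:
            raise ValueError("no low-ITH candidate is present in every training cohort")
        screen = cox_screen(
            self.train_cohorts, candidates, alpha=self.alpha, method=self.screen_method
        )
        if not screen.passed:
            raise ValueError("Cox screen left no gene; relax alpha or check cohorts")
        directions = {g: -1 for g in screen.protective}
        directions.update({g: 1 for g in screen.risk})
        stable, counts = bootstrap_stability(
            self.train_cohorts,
            screen.passed,
            directions=directions,
            n_boot=self.n_boot,
            pass_fraction=self.pass_fraction,
            alpha=self.alpha,
            seed=seed,
            method=self.bootstrap_method,
        )
        if len(stable) < 2:
            raise ValueError("fewer than 2 bootstrap-stable genes; cannot search combinations")
        forest = forest_combination_search(
            self.train_cohorts,
            stable,
            n_replicates=self.n_replicates,
            n_trees=self.n_trees,
            max_subset=self.max_subset,
            seed=seed,
        )
        weights = fit_signature_weights(self.train_cohorts, forest.genes)
        model = SignatureModel(
            genes=forest.genes,
            weights=weights,
            directions={g: ("risk" if weights[g] >= 0 else "protective") for g in forest.genes},
            score_rule="cox_linear_predictor",
            training_meta={
                "cohorts": [c.name for c in self.train_cohorts],
                "ihs_threshold": self.ihs_threshold,
                "alpha": self.alpha,
                "n_boot": self.n_boot,
                "pass_fraction": self.pass_fraction,
                "seed": seed,
            },
        )
        return SignatureResults(
            builder=self,
            model=model,
            screen=screen,
            stable_genes=stable,
            bootstrap_counts=counts,
            forest=forest,
        )


@dataclass
class SignatureResults:
    """Everything the signature build produced, with evaluation helpers."""

    builder: LowITHSignatureModel
    model: SignatureModel
    screen: CoxScreenResult = field(repr=False)
    stable_genes: list[str] = field(default_factory=list)
    bootstrap_counts: pd.Series = field(default_factory=pd.Series, repr=False)
    forest: ForestSearchResult | None = field(default=None, repr=False)

    def evaluate_prognosis(self, cohorts, **kw) -> pd.DataFrame:
        return evaluate_prognosis(self.model, cohorts, **kw)

    def evaluate_ith_robustness(self, expression, patients, ihs_values, **kw):
        return evaluate_ith_robustness(self.model, expression, patients, ihs_values, **kw)

    def summary(self) -> str:
        lines = [
            "Low-ITH prognostic signature",
            "=" * 30,
            f"training cohorts:   {', '.join(c.name for c in self.builder.train_cohorts)}",
            f"screen pass:        {len(self.screen.protective)} protective, "
            f"{len(self.screen.risk)} risk",
            f"bootstrap-stable:   {len(self.stable_genes)}",
            f"signature size:     {len(self.model.genes)}",
            f"OOB concordance:    {self.forest.best_concordance:.3f}"
            + ("  (low confidence)" if self.forest.low_confidence else ""),
            "",
            "genes and weights:",
        ]
        for g in self.model.genes:
            lines.append(f"  {g:<12} {self.model.weights[g]:+.4f}  ({self.model.directions[g]})")
        return "\n".join(lines)
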