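"""Multiple imputation of mixed-type phenotypes by chained equations.

Missing cells are filled iteratively, one trait at a time, conditioning
on all other traits. Quantitative traits use predictive mean matching
(PMM) against a Bayesian linear regression: a ridge-stabilised posterior
draw of the coefficients predicts the missing cells, and each is replaced
by the observed value of one of the 5 donors with the closest predicted
mean, so imputations are always plausible observed values. Qualitative
traits are imputed by a draw from the predictive category distribution of
a ridge-penalised multinomial logistic regression (penalty lambda = 1/n),
whose shrinkage also absorbs separation and collinearity in the
predictors. Traits are visited in ascending missing-rate order, so each
model conditions on the most complete data available.

Several independent chains are run from random initial fills; convergence
is monitored by the Gelman-Rubin potential scale reduction factor (R-hat)
on the per-trait mean and SD (mode frequency for qualitative traits) of
the imputed cells, with the usual < 1.1 rule. M completed datasets are
collected from post-burn-in states across chains and may be pooled to a
single consensus table (cell-wise mean / modal level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .schema import PhenotypeTable

PMM_DONORS = 5
DEFAULT_CHAINS = 4
DEFAULT_ITER = 30
DEFAULT_M = 30
RHAT_THRESHOLD = 1.1


@dataclass
class ImputationResult:
    """M completed tables plus per-chain convergence traces."""

    completed_tables: list[PhenotypeTable]
    chain_trace: dict[str, np.ndarray]  # trait -> (n_chains, n_iter, 2)
    rhat: dict[str, float]
    converged: bool
    M: int
    n_chains: int

    def rhat_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.rhat.items()), columns=["statistic", "rhat"]
        )


def rhat(chains) -> float:
    """Gelman-Rubin potential scale reduction factor sqrt(V-hat / W).

    ``chains`` is a sequence of >= 2 equal-length scalar sequences with
    >= 2 retained iterations each. Identical constant chains return 1.0
    (the defined limit).
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 iterations each")
    m, n = arr.shape
    chain_means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B_over_n = chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


def _design(table: PhenotypeTable, exclude: str) -> np.ndarray:
    """Predictor matrix from all traits but one (qualitative dummy-expanded)."""
    cols = [np.ones(table.n)]
    for spec in table.schema:
        if spec.name == exclude:
            continue
        if spec.is_quantitative:
            x = table.data[spec.name].to_numpy(dtype=float)
            sd = np.nanstd(x)
            cols.append((x - np.nanmean(x)) / sd if sd > 0 else np.zeros_like(x))
        else:
            col = table.data[spec.name]
            levels = [lv for lv in spec.levels if lv in set(col.dropna())]
            for lv in levels[1:]:  # reference coding
                cols.append((col == lv).to_numpy(dtype=float))
    return np.column_stack(cols)


def _impute_quantitative(
    y: np.ndarray, X: np.ndarray, miss: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """PMM draw for the missing entries of y given completed predictors X."""
    obs = ~miss
    Xo, yo = X[obs], y[obs]
    n_obs, p = Xo.shape
    lam = 1e-4 * n_obs  # mild ridge; rescues singular designs
    XtX = Xo.T @ Xo + lam * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ Xo.T @ yo
    resid = yo - Xo @ beta_hat
    dof = max(n_obs - p, 1)
    sigma2 = float(resid @ resid) / dof
    # posterior draws: sigma2* ~ scaled-inv-chi2, beta* ~ N(beta_hat, sigma2* (X'X)^-1)
    sigma2_star = sigma2 * dof / stats.chi2.rvs(dof, random_state=rng)
    beta_star = rng.multivariate_normal(
        beta_hat, sigma2_star * XtX_inv, method="cholesky"
    )
    pred_obs = Xo @ beta_hat
    pred_mis = X[miss] @ beta_star
    out = np.empty(int(miss.sum()))
    n_donor = min(PMM_DONORS, n_obs)
    for i, pm in enumerate(pred_mis):
        donors = np.argsort(np.abs(pred_obs - pm), kind="stable")[:n_donor]
        out[i] = yo[donors[int(rng.integers(n_donor))]]
    return out


def _impute_qualitative(
    col: pd.Series,
    X: np.ndarray,
    miss: np.ndarray,
    levels: list[str],
    rng: np.random.Generator,
) -> list[str]:
    """Predictive-category draw from a ridge multinomial regression."""
    obs = ~miss
    yo = col[obs].to_numpy(dtype=object)
    present = [lv for lv in levels if lv in set(yo)]
    if len(present) == 1:
        return [present[0]] * int(miss.sum())
    # sklearn's C is the inverse penalty; lambda = 1/n  =>  C = n
    model = LogisticRegression(C=float(len(yo)), max_iter=1000)
    model.fit(X[obs], yo)
    probs = model.predict_proba(X[miss])
    classes = list(model.classes_)
    draws = [
        classes[rng.choice(len(classes), p=p / p.sum())] for p in probs
    ]
    return draws


def _initial_fill(
    table: PhenotypeTable, rng: np.random.Generator
) -> PhenotypeTable:
    """Fill every missing cell with a draw from the trait's observed values."""
    out = table.copy()
    for spec in table.schema:
        col = out.data[spec.name]
        miss = col.isna().to_numpy()
        if not miss.any():
            continue
        observed = col.dropna().to_numpy()
        if observed.size == 0:
            raise ValueError(f"trait {spec.name!r} has no observed values")
        fills = observed[rng.integers(observed.size, size=int(miss.sum()))]
        out.data.loc[miss, spec.name] = fills
    return PhenotypeTable(out.data, out.schema)


def _trace_stats(values: np.ndarray, quantitative: bool) -> tuple[float, float]:
    if quantitative:
        v = values.astype(float)
        return float(v.mean()), float(v.std())
    # qualitative: modal frequency plays the role of the mean; its
    # complement spread plays the role of the SD
    _, counts = np.unique(values.astype(str), return_counts=True)
    p = counts.max() / counts.sum()
    return float(p), float(1.0 - p)


def impute_chained(
    table: PhenotypeTable,
    n_chains: int = DEFAULT_CHAINS,
    n_iter: int = DEFAULT_ITER,
    M: int = DEFAULT_M,
    seed: int = 0,
) -> ImputationResult:
    """Run chained-equation multiple imputation with multi-chain R-hat.

    Burn-in is the first half of ``n_iter``; the M completed tables are
    taken from the post-burn-in iterations, spread evenly across chains
    (cycling when M exceeds the number of retained states). Observed
    cells are never altered. A table without missing cells returns M
    identical copies with an empty R-hat table.
    """
    if table.n < 10:
        raise ValueError("need at least 10 accessions to impute")
    miss_rates = {s.name: table.missing_rate(s.name) for s in table.schema}
    if any(r >= 1.0 for r in miss_rates.values()):
        fully = [t for t, r in miss_rates.items() if r >= 1.0]
        raise ValueError(f"trait(s) with zero observed values: {fully}")

    traits_with_missing = [t for t, r in miss_rates.items() if r > 0]
    if not traits_with_missing:
        return ImputationResult(
            completed_tables=[table.copy() for _ in range(M)],
            chain_trace={},
            rhat={},
            converged=True,
            M=M,
            n_chains=n_chains,
        )
    # ascending missing rate: condition on the most complete data first
    visit_order = sorted(traits_with_missing, key=lambda t: (miss_rates[t], t))
    miss_masks = {t: table.data[t].isna().to_numpy() for t in visit_order}

    burn_in = n_iter // 2
    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(2**31, size=n_chains)

    trace: dict[str, np.ndarray] = {
        t: np.empty((n_chains, n_iter, 2)) for t in visit_order
    }
    retained: list[list[PhenotypeTable]] = []

    for c in range(n_chains):
        crng = np.random.default_rng(chain_seeds[c])
        current = _initial_fill(table, crng)
        kept: list[PhenotypeTable] = []
        for it in range(n_iter):
            for t in visit_order:
                spec = table.schema[t]
                miss = miss_masks[t]
                # re-expose the missing cells so the model sees observed only
                X = _design(current, t)
                if spec.is_quantitative:
                    y = current.data[t].to_numpy(dtype=float).copy()
                    y[miss] = np.nan
                    fills = _impute_quantitative(y, X, miss, crng)
                else:
                    col = table.data[t]  # observed pattern from the input
                    fills = _impute_qualitative(
                        col, X, miss, list(spec.levels), crng
                    )
                current.data.loc[miss, t] = fills
                trace[t][c, it] = _trace_stats(
                    current.data.loc[miss, t].to_numpy(),
                    spec.is_quantitative,
                )
            if it >= burn_in:
                kept.append(current.copy())
        retained.append(kept)

    rhats: dict[str, float] = {}
    for t in visit_order:
        post = trace[t][:, burn_in:, :]
        rhats[f"{t}:mean"] = rhat(post[:, :, 0])
        rhats[f"{t}:sd"] = rhat(post[:, :, 1])
    converged = all(v < RHAT_THRESHOLD for v in rhats.values())

    # interleave post-burn-in states across chains, newest last, cycle to M
    pool: list[PhenotypeTable] = []
    max_len = max(len(k) for k in retained)
    for i in range(max_len):
        for c in range(n_chains):
            if i < len(retained[c]):
                pool.append(retained[c][i])
    completed = [pool[i % len(pool)] for i in range(M)]

    return ImputationResult(
        completed_tables=completed,
        chain_trace=trace,
        rhat=rhats,
        converged=converged,
        M=M,
        n_chains=n_chains,
    )


def pool_completed(
    result: ImputationResult, rule: str = "consensus", force: bool = False
) -> PhenotypeTable:
    """Collapse M completed tables to one.

    ``consensus``: quantitative cells are averaged across the M tables;
    qualitative cells take the modal level, ties broken by the higher
    marginal frequency in the pooled tables, then by level order.
    ``first``: completed table #1 as-is.
    """
    if not result.converged and not force:
        raise ValueError(
            "imputation chains not converged (R-hat >= 1.1); "
            "pass force=True to pool anyway"
        )
    tables = result.completed_tables
    if rule == "first":
        return tables[0].copy()
    if rule != "consensus":
        raise ValueError(f"unknown pooling rule {rule!r}")
    out = tables[0].copy()
    for spec in out.schema:
        if spec.is_quantitative:
            stack = np.column_stack(
                [t.data[spec.name].to_numpy(dtype=float) for t in tables]
            )
            out.data[spec.name] = stack.mean(axis=1)
        else:
            stack = pd.DataFrame(
                {i: t.data[spec.name] for i, t in enumerate(tables)}
            )
            marginal = stack.stack().value_counts()
            level_rank = {lv: i for i, lv in enumerate(spec.levels)}
            pooled = []
            for _, row in stack.iterrows():
                counts = row.value_counts()
                best = sorted(
                    counts.index,
                    key=lambda lv: (
                        -counts[lv],
                        -marginal.get(lv, 0),
                        level_rank.get(lv, len(level_rank)),
                    ),
                )[0]
                pooled.append(best)
            out.data[spec.name] = pooled
    return PhenotypeTable(out.data, out.schema)


def compare_observed_vs_imputed(
    original: PhenotypeTable, pooled: PhenotypeTable
) -> pd.DataFrame:
    """Per-trait tests of observed-only vs completed samples.

    Quantitative traits: pooled-variance two-sample t-test between the
    observed cells of the original table and the full completed column.
    Qualitative traits: chi-squared homogeneity between observed counts
    and completed counts (Yates-corrected when 2x2). A trait constant in
    both samples gets p = 1 by convention.
    """
    from .evaluation_stats import chi2_homogeneity, mean_difference_test

    if original.schema.names != pooled.schema.names:
        raise ValueError("schemas differ")
    rows = []
    for spec in original.schema:
        if spec.is_quantitative:
            obs = original.data[spec.name].dropna().to_numpy(dtype=float)
            full = pooled.data[spec.name].to_numpy(dtype=float)
            res = mean_difference_test(obs, full, levene_p=1.0)
            rows.append(
                {
                    "trait": spec.name,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p": res.p,
                }
            )
        else:
            order = [
                lv
                for lv in spec.levels
                if lv in set(original.data[spec.name].dropna())
                or lv in set(pooled.data[spec.name].dropna())
            ]
            a = [int((original.data[spec.name] == lv).sum()) for lv in order]
            b = [int((pooled.data[spec.name] == lv).sum()) for lv in order]
            res = chi2_homogeneity(a, b)
            rows.append(
                {
                    "trait": spec.name,
                    "test": res.test,
                    "statistic": res.statistic,
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows)
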