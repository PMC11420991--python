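"""Group comparisons and environmental coupling.

One-way ANOVA with Tukey-HSD compact letters, Spearman correlation panels
(dominant phyla or NCI vs soil variables), redundancy analysis (RDA) of
the Hellinger-transformed community on z-scored environment variables,
random-forest permutation importance for the NCI, and the alpha-diversity
vs environment Mantel preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import (
    DistanceMatrix,
    DiversityResult,
    MantelResult,
    euclidean_distance,
    mantel,
)
from .io import CountTable

__all__ = [
    "AnovaResult",
    "CorrPanel",
    "RdaResult",
    "RfImportance",
    "one_way_anova",
    "spearman_panel",
    "rda",
    "rf_importance",
    "alpha_env_mantel_preset",
    "benjamini_hochberg",
]


@dataclass
class AnovaResult:
    variable: str
    f: float
    p: float
    group_means: pd.Series
    group_sds: pd.Series
    letters: dict[str, str]


@dataclass
class CorrPanel:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    flagged_constant: list[str]


@dataclass
class RdaResult:
    eigenvalues: np.ndarray
    constrained_proportion: float
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    env_scores: pd.DataFrame


@dataclass
class RfImportance:
    importances: pd.Series  # variable -> permutation importance, sorted desc
    n_trees: int
    seed: int

    @property
    def ranking(self) -> list[str]:
        return list(self.importances.index)


# ---------------------------------------------------------------------------
# ANOVA + compact letter display
# ---------------------------------------------------------------------------

def _compact_letters(
    groups: list[str], not_different: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; groups with
    no shared letter differ. Letters are assigned deterministically in
    group order.
    """
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all((min(g, h), max(g, h)) in not_different for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb sets contained in others
    letter_sets = [
        s
        for i, s in enumerate(letter_sets)
        if not any(i != j and s < t for j, t in enumerate(letter_sets))
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def one_way_anova(
    values_by_group: dict[str, np.ndarray],
    variable: str = "",
    alpha: float = 0.05,
) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD post-hoc letters."""
    groups = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    if pooled.var() == 0:
        raise ValueError("zero variance everywhere; ANOVA undefined")
    f, p = sps.f_oneway(*arrays)
    not_different: set[tuple[str, str]] = set()
    if len(groups) >= 2:
        tk = sps.tukey_hsd(*arrays)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if tk.pvalue[i, j] >= alpha:
                    a, b = groups[i], groups[j]
                    not_different.add((min(a, b), max(a, b)))
    letters = _compact_letters(groups, not_different)
    return AnovaResult(
        variable=variable,
        f=float(f),
        p=float(p),
        group_means=pd.Series({g: a.mean() for g, a in zip(groups, arrays)}),
        group_sds=pd.Series(
            {g: a.std(ddof=1) for g, a in zip(groups, arrays)}
        ),
        letters=letters,
    )


# ---------------------------------------------------------------------------
# Spearman panel
# ---------------------------------------------------------------------------

def spearman_panel(x: pd.DataFrame, y: pd.DataFrame) -> CorrPanel:
    """Pairwise Spearman r / p between columns of ``x`` (rows of the panel)
    and columns of ``y``, with 0.05 / 0.01 significance stars."""
    if not x.index.equals(y.index):
        raise ValueError("sample ids of the two matrices must match")
    r = pd.DataFrame(index=x.columns, columns=y.columns, dtype=float)
    p = pd.DataFrame(index=x.columns, columns=y.columns, dtype=float)
    flagged = []
    for cx in x.columns:
        if np.std(x[cx].to_numpy()) == 0:
            flagged.append(str(cx))
        for cy in y.columns:
            if (
                np.std(x[cx].to_numpy()) == 0
                or np.std(y[cy].to_numpy()) == 0
            ):
                r.loc[cx, cy], p.loc[cx, cy] = 0.0, 1.0
                continue
            res = sps.spearmanr(x[cx], y[cy])
            r.loc[cx, cy], p.loc[cx, cy] = res.statistic, res.pvalue
    stars = p.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    return CorrPanel(r=r, p=p, stars=stars, flagged_constant=flagged)


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

def rda(community: CountTable | np.ndarray, env: pd.DataFrame) -> RdaResult:
    """Redundancy analysis of the community on environment variables.

    The community is Hellinger-transformed (when a count table is given)
    and column-centered; environment variables are z-scored; the
    constrained axes are the principal components of the fitted values of
    the multivariate least-squares regression of community on environment.
    The constrained proportion is the fitted share of total variance.
    """
    from .diversity import hellinger

    if isinstance(community, CountTable):
        ids = list(community.sample_ids)
        y = hellinger(community)
        species = list(community.otu_ids)
    else:
        y = np.asarray(community, dtype=float)
        ids = list(env.index)
        species = [f"var{i}" for i in range(y.shape[1])]
    x = env.to_numpy(dtype=float)
    n, q = x.shape
    if q < 2:
        raise ValueError("need at least 2 environment variables")
    if n <= q:
        raise ValueError("need more samples than environment variables")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(env.columns, sd) if s == 0]
        raise ValueError(f"constant environment column(s): {bad}")
    xs = (x - x.mean(axis=0)) / sd
    # collinearity check
    rank = np.linalg.matrix_rank(xs, tol=1e-8)
    if rank < q:
        corr = np.corrcoef(xs, rowvar=False)
        iu = np.triu_indices(q, 1)
        k = np.argmax(np.abs(corr[iu]))
        pair = (env.columns[iu[0][k]], env.columns[iu[1][k]])
        raise ValueError(f"collinear environment columns, e.g. {pair}")
    yc = y - y.mean(axis=0)
    beta, *_ = np.linalg.lstsq(xs, yc, rcond=None)
    fitted = xs @ beta
    total_var = float((yc**2).sum())
    fitted_var = float((fitted**2).sum())
    prop = fitted_var / total_var if total_var > 0 else 0.0
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    k_axes = min(rank, len(s))
    eig = (s[:k_axes] ** 2) / max(n - 1, 1)
    axes = [f"RDA{i + 1}" for i in range(k_axes)]
    site = pd.DataFrame(u[:, :k_axes] * s[:k_axes], index=ids, columns=axes)
    # scaling 2: species scores carry the eigenvalue weight
    spec = pd.DataFrame(vt[:k_axes].T * np.sqrt(eig), index=species, columns=axes)
    envs = pd.DataFrame(
        np.corrcoef(np.hstack([xs, site.to_numpy()]), rowvar=False)[
            :q, q:
        ],
        index=env.columns,
        columns=axes,
    )
    return RdaResult(
        eigenvalues=eig,
        constrained_proportion=prop,
        site_scores=site,
        species_scores=spec,
        env_scores=envs,
    )


# ---------------------------------------------------------------------------
# Random forest importance
# ---------------------------------------------------------------------------

def rf_importance(
    y: np.ndarray | pd.Series,
    x: pd.DataFrame,
    n_trees: int = 1000,
    seed: int = 0,
    n_repeats: int = 10,
) -> RfImportance:
    """Permutation importance of each environment variable for the NCI.

    A regression random forest is fit on a seeded 70% split; importance of
    a variable is the mean increase in squared error on the held-out 30%
    when that variable is permuted (averaged over ``n_repeats`` shuffles).
    Scoring on held-out data keeps memorized noise from inflating the
    importance of irrelevant variables.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance

    yv = np.asarray(y, dtype=float)
    if len(yv) < 10:
        raise ValueError("need at least 10 observations")
    if yv.std() == 0:
        raise ValueError("constant response; importance undefined")
    rng = np.random.default_rng(int(seed))
    n = len(yv)
    perm = rng.permutation(n)
    n_train = max(int(round(0.7 * n)), 2)
    train, test = perm[:n_train], perm[n_train:]
    if len(test) < 2:
        train, test = perm, perm
    xv = x.to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=n_trees, random_state=int(seed) % (2**31), n_jobs=1
    )
    rf.fit(xv[train], yv[train])
    pi = permutation_importance(
        rf,
        xv[test],
        yv[test],
        n_repeats=n_repeats,
        random_state=(int(seed) + 1) % (2**31),
        n_jobs=1,
    )
    imp = pd.Series(pi.importances_mean, index=x.columns).sort_values(
        ascending=False
    )
    return RfImportance(importances=imp, n_trees=n_trees, seed=seed)


# ---------------------------------------------------------------------------
# Mantel preset + BH
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up FDR)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def alpha_env_mantel_preset(
    diversity: DiversityResult,
    env: pd.DataFrame,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel tests between the alpha-diversity distance matrix and the
    per-variable environment distances.

    Alpha indices are pooled into one Euclidean distance on z-scored
    (observed OTUs, Shannon, ACE); each environment variable yields its
    own Euclidean distance on the z-scored values. Raw p-values are
    reported alongside Benjamini–Hochberg adjusted ones.
    """
    div = diversity.to_dataframe()
    ids = list(div.index)
    if not env.index.equals(div.index):
        env = env.loc[ids]
    d_alpha = euclidean_distance(div.to_numpy(), ids)
    rows = []
    for i, var in enumerate(env.columns):
        d_env = euclidean_distance(env[var].to_numpy(), ids)
        res: MantelResult = mantel(
            d_alpha, d_env, method=method, n_perm=n_perm, seed=seed + i
        )
        rows.append({"variable": var, "r": res.r, "p": res.p, "n_perm": n_perm})
    out = pd.DataFrame(rows).set_index("variable")
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out
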