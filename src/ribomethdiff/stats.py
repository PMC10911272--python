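"""Donor-blocked differential testing and sample embedding of RMS scores.

Each site's scores across the donor x state grid are modelled with an
additive two-factor fixed-effects ANOVA, y = mu + donor + state + eps,
so the donor batch effect is blocked out before comparing growth states.
For a balanced design with a states and b donors (one biological sample
per cell) the state test uses

    F = MS_state / MS_residual,  df = (a - 1), (a - 1)(b - 1)

computed from the exact sums-of-squares decomposition.  Omnibus p-values
are Benjamini-Hochberg adjusted across sites (discovery cutoff q < 0.1),
and pairwise state contrasts use Tukey's studentized-range test on the
blocked model's residual mean square.  For visualisation, samples are
embedded in 2-D (t-SNE, PCA fallback), optionally after eliminating the
donor factor by donor-mean centring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score, pairwise_distances

from .design import StudyDesign
from .scoring import RMSScoreTable

__all__ = [
    "SiteTestResult",
    "EmbeddingResult",
    "OptimalK",
    "blocked_anova_arrays",
    "fit_blocked_anova",
    "bh_adjust",
    "tukey_pairwise",
    "classify_sites",
    "eliminate_factor",
    "embed_samples",
    "silhouette_optimal_k",
    "nearest_neighbor_label_agreement",
    "results_to_frame",
]

#: residual sums-of-squares below this fraction of total SS count as zero
_ZERO_SS_REL_TOL = 1e-12


@dataclass
class SiteTestResult:
    site: str
    group_means: dict[str, float] = field(default_factory=dict)
    f_state: float = float("nan")
    p_state: float = float("nan")
    q_state: float = float("nan")
    tukey_p: dict[tuple[str, str], float] = field(default_factory=dict)
    classification: str | None = None
    flags: tuple[str, ...] = ()
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


class OptimalK(NamedTuple):
    best_k: int
    silhouette: float
    by_k: dict[int, float]
    weak: bool


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame  # samples x (dim1, dim2)
    eliminated_factor: str  # "none" or "donor"
    seed: int
    method: str

    def write(self, path) -> None:
        self.coords.to_csv(path, sep="\t", index_label="sample", float_format="%.6g")


def _grid(scores: pd.DataFrame, design: StudyDesign) -> tuple[np.ndarray, list, list]:
    """Arrange site x sample scores into (sites, states, donors) with NaN holes."""
    bio = design.biological_design()
    if not bio.is_complete_crossing():
        raise ValueError("blocked ANOVA requires a complete donor x state crossing")
    states, donors = list(bio.states), list(bio.donors)
    cell_sample: dict[tuple[str, str], str] = {}
    for s in bio:
        if (s.state, s.donor) in cell_sample:
            raise ValueError(
                "balanced design required: more than one biological sample in cell "
                f"({s.donor}, {s.state})"
            )
        cell_sample[(s.state, s.donor)] = s.sample_id
    missing = [sid for sid in cell_sample.values() if sid not in scores.columns]
    if missing:
        raise KeyError(f"design samples absent from score table: {missing}")
    y = np.empty((scores.shape[0], len(states), len(donors)))
    for i, st in enumerate(states):
        for j, d in enumerate(donors):
            y[:, i, j] = scores[cell_sample[(st, d)]].to_numpy(dtype=float)
    return y, states, donors


def blocked_anova_arrays(y: np.ndarray) -> dict[str, np.ndarray]:
    """Exact two-way (state + block) decomposition on stacked balanced tables.

    ``y`` has shape (..., a_states, b_blocks), one observation per cell.
    Returns F and p for the state factor plus the SS pieces; degenerate
    zero-residual tables get p = 0 (nonzero state SS) or F = 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    a, b = y.shape[-2], y.shape[-1]
    grand = y.mean(axis=(-1, -2), keepdims=True)
    state_means = y.mean(axis=-1, keepdims=True)
    donor_means = y.mean(axis=-2, keepdims=True)
    ss_state = b * ((state_means - grand) ** 2).sum(axis=(-1, -2))
    ss_donor = a * ((donor_means - grand) ** 2).sum(axis=(-1, -2))
    ss_total = ((y - grand) ** 2).sum(axis=(-1, -2))
    ss_resid = np.maximum(ss_total - ss_state - ss_donor, 0.0)
    df_state, df_resid = a - 1, (a - 1) * (b - 1)

    tol = _ZERO_SS_REL_TOL * np.maximum(ss_total, 1.0)
    zero_resid = ss_resid <= tol
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_state / df_state) / (ss_resid / df_resid)
    p = sps.f.sf(f, df_state, df_resid)
    # degenerate cases
    null_effect = ss_state <= tol
    f = np.where(zero_resid & null_effect, 0.0, f)
    p = np.where(zero_resid & null_effect, 1.0, p)
    f = np.where(zero_resid & ~null_effect, np.inf, f)
    p = np.where(zero_resid & ~null_effect, 0.0, p)
    return {
        "f": f,
        "p": p,
        "ss_state": ss_state,
        "ss_donor": ss_donor,
        "ss_resid": ss_resid,
        "df_state": df_state,
        "df_resid": df_resid,
        "ms_resid": ss_resid / df_resid,
        "zero_residual": zero_resid,
    }


def fit_blocked_anova(
    scores: RMSScoreTable | pd.DataFrame, design: StudyDesign
) -> list[SiteTestResult]:
    """Per-site donor-blocked ANOVA of the state factor.

    Sites with any missing (donor, state) cell are skipped with a reason
    rather than fitted on an unbalanced table.
    """
    df = scores.scores if isinstance(scores, RMSScoreTable) else scores
    y, states, donors = _grid(df, design)
    results: list[SiteTestResult] = []
    complete = ~np.isnan(y).any(axis=(-1, -2))
    stats = blocked_anova_arrays(np.where(np.isnan(y), 0.0, y))
    for i, site in enumerate(df.index):
        if not complete[i]:
            n_missing = int(np.isnan(y[i]).sum())
            results.append(
                SiteTestResult(
                    site=site,
                    skipped_reason=f"{n_missing} missing cell(s) in the donor x state grid",
                )
            )
            continue
        means = {st: float(y[i, k, :].mean()) for k, st in enumerate(states)}
        flags = ("zero_residual",) if stats["zero_residual"][i] else ()
        results.append(
            SiteTestResult(
                site=site,
                group_means=means,
                f_state=float(stats["f"][i]),
                p_state=float(stats["p"][i]),
                flags=flags,
            )
        )
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries propagate as NaN
    and do not count toward the number of tests."""
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    pv = p[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        qs = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.minimum(qs, 1.0)
        q[valid] = qv
    return q


def tukey_pairwise(
    scores: RMSScoreTable | pd.DataFrame,
    design: StudyDesign,
    site: str,
) -> dict[tuple[str, str], float]:
    """Tukey studentized-range p for every state pair at one site, using the
    blocked model's residual mean square and degrees of freedom."""
    df = scores.scores if isinstance(scores, RMSScoreTable) else scores
    y, states, donors = _grid(df.loc[[site]], design)
    if np.isnan(y).any():
        raise ValueError(f"site {site}: missing cells, cannot run pairwise contrasts")
    stats = blocked_anova_arrays(y)
    ms_resid = float(stats["ms_resid"][0])
    df_resid = stats["df_resid"]
    b = len(donors)
    a = len(states)
    means = {st: float(y[0, k, :].mean()) for k, st in enumerate(states)}
    out: dict[tuple[str, str], float] = {}
    for i in range(a):
        for j in range(i + 1, a):
            pair = (states[i], states[j])
            diff = abs(means[states[i]] - means[states[j]])
            if stats["zero_residual"][0]:
                out[pair] = 0.0 if diff > 0 else 1.0
                continue
            q_obs = diff / np.sqrt(ms_resid / b)
            out[pair] = float(sps.studentized_range.sf(q_obs, a, df_resid))
    return out


def classify_sites(
    results: list[SiteTestResult],
    scores: RMSScoreTable | pd.DataFrame,
    high_cutoff: float = 0.9,
    q_cutoff: float = 0.1,
) -> list[SiteTestResult]:
    """Fill classifications: ``variable`` (q below cutoff), else
    ``constitutive_high`` (grand mean score above ``high_cutoff``), else
    ``substoichiometric_stable``.  Mutates and returns ``results``."""
    df = scores.scores if isinstance(scores, RMSScoreTable) else scores
    grand_means = df.mean(axis=1, skipna=True)
    for r in results:
        if r.skipped:
            continue
        if not np.isnan(r.q_state) and r.q_state < q_cutoff:
            r.classification = "variable"
        elif grand_means.get(r.site, np.nan) > high_cutoff:
            r.classification = "constitutive_high"
        else:
            r.classification = "substoichiometric_stable"
    return results


def eliminate_factor(
    scores: RMSScoreTable | pd.DataFrame,
    design: StudyDesign,
    factor: str = "donor",
) -> pd.DataFrame:
    """Remove a blocking factor from the score matrix by level-mean centring.

    Per site: subtract the factor-level mean and add back the grand mean,
    NaN-aware; shape and missingness are preserved.  Idempotent.
    """
    if factor not in ("donor", "state"):
        raise ValueError(f"unknown factor {factor!r}")
    df = (scores.scores if isinstance(scores, RMSScoreTable) else scores).copy()
    bio = design.biological_design()
    levels: dict[str, str] = {
        s.sample_id: (s.donor if factor == "donor" else s.state) for s in bio
    }
    unknown = [c for c in df.columns if c not in levels]
    if unknown:
        raise KeyError(f"samples not in design: {unknown}")
    level_of = pd.Series({c: levels[c] for c in df.columns})
    for lev in level_of.unique():
        cols = level_of.index[level_of == lev]
        if len(cols) == 0:
            raise ValueError(f"factor level {lev!r} has no samples")
    grand = df.mean(axis=1, skipna=True)
    adjusted = df.copy()
    for lev in level_of.unique():
        cols = level_of.index[level_of == lev]
        level_mean = df[cols].mean(axis=1, skipna=True)
        adjusted[cols] = df[cols].sub(level_mean, axis=0).add(grand, axis=0)
    return adjusted


def embed_samples(
    scores: RMSScoreTable | pd.DataFrame,
    seed: int = 0,
    method: str = "tsne",
    perplexity: float = 3.0,
    eliminated_factor: str = "none",
) -> EmbeddingResult:
    """Deterministic 2-D embedding of samples from the site x sample matrix.

    Missing cells are imputed with the site mean.  The perplexity is
    clamped below the number of samples; ``method="pca"`` provides a
    linear fallback for very small n.
    """
    df = scores.scores if isinstance(scores, RMSScoreTable) else scores
    X = df.to_numpy(dtype=float).T  # samples x sites
    n = X.shape[0]
    if n < 3:
        raise ValueError("embedding requires at least 3 samples")
    # site-mean imputation
    col_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    nan_ix = np.isnan(X)
    X[nan_ix] = np.take(col_means, np.nonzero(nan_ix)[1])
    if method == "tsne":
        perp = min(float(perplexity), (n - 1) / 1.0000001)
        model = TSNE(
            n_components=2,
            perplexity=perp,
            random_state=int(seed),
            init="pca",
            learning_rate="auto",
        )
        coords = model.fit_transform(X)
    elif method == "pca":
        coords = PCA(n_components=2, random_state=int(seed)).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return EmbeddingResult(
        coords=pd.DataFrame(coords, index=df.columns, columns=["dim1", "dim2"]),
        eliminated_factor=eliminated_factor,
        seed=int(seed),
        method=method,
    )


def silhouette_optimal_k(
    coords: pd.DataFrame | np.ndarray,
    k_range: tuple[int, int] = (2, 5),
    seed: int = 0,
    weak_threshold: float = 0.5,
) -> OptimalK:
    """Cluster count maximizing the mean silhouette of seeded k-means.

    Ties break toward the smaller k.  A best silhouette at or below
    ``weak_threshold`` is flagged as weak: by the usual reading of
    silhouette widths, values <= 0.5 indicate structure that may be
    artificial (an unstructured blob partitions at ~0.3-0.45), while
    genuinely separated groups score well above it.
    """
    X = coords.to_numpy() if isinstance(coords, pd.DataFrame) else np.asarray(coords)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to choose a cluster count")
    lo, hi = k_range
    lo = max(2, lo)
    hi = min(hi, n - 1)
    if lo > hi:
        raise ValueError(f"empty k range after clamping to [2, {n - 1}]")
    by_k: dict[int, float] = {}
    for k in range(lo, hi + 1):
        labels = KMeans(n_clusters=k, n_init=10, random_state=int(seed)).fit_predict(X)
        if len(np.unique(labels)) < 2:
            by_k[k] = -1.0
            continue
        by_k[k] = float(silhouette_score(X, labels))
    best_k = max(by_k, key=lambda k: (by_k[k], -k))
    return OptimalK(best_k, by_k[best_k], by_k, by_k[best_k] <= weak_threshold)


def nearest_neighbor_label_agreement(
    coords: pd.DataFrame | np.ndarray, labels: Sequence[str]
) -> float:
    """Fraction of points whose nearest 2-D neighbour carries the same label."""
    X = coords.to_numpy() if isinstance(coords, pd.DataFrame) else np.asarray(coords)
    labels = np.asarray(labels)
    D = pairwise_distances(X)
    np.fill_diagonal(D, np.inf)
    nn = D.argmin(axis=1)
    return float((labels[nn] == labels).mean())


def results_to_frame(results: list[SiteTestResult]) -> pd.DataFrame:
    """Flatten test results to one row per site for TSV export."""
    rows = []
    for r in results:
        row: dict = {"site": r.site, "skipped_reason": r.skipped_reason or ""}
        for st, m in r.group_means.items():
            row[f"mean_{st}"] = m
        row.update(
            f_state=r.f_state,
            p_state=r.p_state,
            q_state=r.q_state,
            classification=r.classification or "",
            flags=";".join(r.flags),
        )
        for (a, b), p in r.tukey_p.items():
            row[f"tukey_p_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("site")
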