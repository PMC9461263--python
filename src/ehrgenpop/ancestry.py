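"""Reference-anchored ancestry inference.

Three tools live here:

1. joint PCA of the merged study+panel genotype matrix, with each variant
   centered at 2p and scaled by sqrt(2p(1-p)) using the joint allele
   frequency;
2. genetically-inferred-ancestry (GIA) assignment: one KNN classifier per
   reference ancestry, run on that ancestry's designated PC pair, with k
   chosen by 10-fold cross-validation on the labeled panel samples.
   "Cluster membership" is the fraction of the k nearest panel neighbors
   carrying the ancestry's label; a sample is assigned a label iff exactly
   one ancestry's membership exceeds the threshold (0.50 continental,
   0.90 subcontinental), otherwise it is Ambiguous;
3. unsupervised admixture estimation: the binomial-mixture log-likelihood

       L(Q, F) = sum_ij [ g_ij log(sum_k q_ik f_kj)
                          + (2 - g_ij) log(sum_k q_ik (1 - f_kj)) ]

   maximized by EM block updates of Q (N x K proportions) and F (K x M
   component frequencies) from random starts, keeping the best likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .matrix import MISSING, GenotypeMatrix

AMBIGUOUS = "Ambiguous"

# continental GIA labels keyed by reference superpopulation, with the PC
# pair that carries the most variance for that ancestry (1-based)
DEFAULT_CONTINENTAL_PCS: dict[str, tuple[int, int]] = {
    "EUR": (1, 2),
    "EAS": (1, 2),
    "AFR": (1, 2),
    "AMR": (2, 3),
    "SAS": (4, 5),
}
SUPERPOP_TO_GIA = {
    "EUR": "EA",
    "AFR": "AA",
    "AMR": "HL",
    "EAS": "EAA",
    "SAS": "SAA",
}
DEFAULT_K_GRID = (5, 10, 15, 20)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------
@dataclass
class PcaModel:
    mean: np.ndarray  # 2 * p_hat per variant
    scale: np.ndarray  # sqrt(2 p (1-p)) per variant
    loadings: np.ndarray  # M x n_pc, orthonormal columns
    explained_variance: np.ndarray
    variant_ids: list[str] = field(default_factory=list)


def fit_pca(merged: GenotypeMatrix, n_pc: int = 10) -> tuple[PcaModel, pd.DataFrame]:
    """Joint PCA on the merged (study + panel) matrix.

    Missing dosages are mean-imputed before standardization. Returns the
    model and a per-sample score table (``sample_id, pc1..pc{n_pc}``).
    """
    if n_pc > min(merged.n_samples, merged.n_variants):
        raise ValueError("n_pc exceeds matrix rank bound")
    x = merged.mean_imputed()
    p = np.clip(merged.allele1_freq(), 1e-9, 1 - 1e-9)
    mean = 2.0 * p
    scale = np.sqrt(2.0 * p * (1.0 - p))
    z = (x - mean) / scale
    # economy SVD; deterministic up to column sign, which we fix below
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    u, s, vt = u[:, :n_pc], s[:n_pc], vt[:n_pc]
    # sign convention: largest-|loading| entry positive
    for c in range(n_pc):
        pivot = np.argmax(np.abs(vt[c]))
        if vt[c, pivot] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u * s
    if s[-1] <= 1e-12 * s[0]:
        raise ValueError("requested more components than the matrix rank")
    model = PcaModel(
        mean=mean,
        scale=scale,
        loadings=vt.T,
        explained_variance=s**2 / merged.n_samples,
        variant_ids=list(merged.variants["id"]),
    )
    table = pd.DataFrame(
        scores, columns=[f"pc{i + 1}" for i in range(n_pc)]
    )
    table.insert(0, "sample_id", merged.samples["id"].to_numpy())
    return model, table


# ----------------------------------------------------------------------
# KNN GIA assignment
# ----------------------------------------------------------------------
@dataclass
class GiaAssignment:
    """Per-sample ancestry call with its KNN membership fraction."""

    table: pd.DataFrame  # sample_id, label, membership, plus per-ancestry columns
    k_per_ancestry: dict


def _select_k(
    coords: np.ndarray,
    labels: np.ndarray,
    k_grid: tuple[int, ...],
    cv_folds: int,
    seed: int,
) -> int:
    """10-fold CV accuracy over the k grid; ties break toward smaller k."""
    best_k, best_acc = None, -1.0
    counts = pd.Series(labels).value_counts()
    folds = min(cv_folds, int(counts.min()))
    for k in sorted(k_grid):
        if k >= len(labels):
            continue
        accs = []
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for train, test in skf.split(coords, labels):
            clf = KNeighborsClassifier(n_neighbors=min(k, len(train)))
            clf.fit(coords[train], labels[train])
            accs.append((clf.predict(coords[test]) == labels[test]).mean())
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    if best_k is None:
        raise ValueError("panel too small for every k in the grid")
    return best_k


def _membership_fraction(
    query: np.ndarray,
    panel_coords: np.ndarray,
    panel_labels: np.ndarray,
    target: str,
    k: int,
) -> np.ndarray:
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(panel_coords, panel_labels)
    idx = clf.kneighbors(query, return_distance=False)
    return (panel_labels[idx] == target).mean(axis=1)


def select_pc_pair(
    panel_scores: pd.DataFrame, labels: np.ndarray, ancestry: str
) -> tuple[int, int]:
    """Pick the two PCs that best separate ``ancestry`` from the rest of the
    panel: per PC, the squared one-vs-rest centroid gap over the pooled
    within-group variance; the top two PCs (ties toward lower index) form
    the classifier plane."""
    pc_cols = [c for c in panel_scores.columns if c.startswith("pc")]
    inside = labels == ancestry
    sep = []
    for c in pc_cols:
        x = panel_scores[c].to_numpy()
        gap = (x[inside].mean() - x[~inside].mean()) ** 2
        within = x[inside].var() + x[~inside].var() + 1e-12
        sep.append(gap / within)
    order = np.argsort(-np.asarray(sep), kind="stable")[:2]
    a, b = sorted(int(i) + 1 for i in order)
    return a, b


def assign_continental_gia(
    scores: pd.DataFrame,
    panel_labels: pd.Series,
    threshold: float = 0.50,
    pc_pairs: dict[str, tuple[int, int]] | None = None,
    gia_names: dict[str, str] | None = None,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    cv_folds: int = 10,
    seed: int = 0,
) -> GiaAssignment:
    """Continental GIA labels for every study sample.

    ``scores`` is the joint PCA score table; ``panel_labels`` maps panel
    sample ids to reference superpopulations. Study samples are all score
    rows absent from ``panel_labels``. Per ancestry, membership is computed
    by a KNN vote on that ancestry's designated PC pair — the pair of PCs
    capturing the most variation for the group, chosen per panel by
    :func:`select_pc_pair` unless fixed via ``pc_pairs`` (the 1000G-style
    convention lives in ``DEFAULT_CONTINENTAL_PCS``). A sample gets the
    ancestry's GIA name iff exactly one membership exceeds ``threshold``,
    else Ambiguous.
    """
    gia_names = dict(SUPERPOP_TO_GIA if gia_names is None else gia_names)
    panel_labels = panel_labels.astype(str)
    is_panel = scores["sample_id"].isin(panel_labels.index).to_numpy()
    study = scores[~is_panel].reset_index(drop=True)
    panel = scores[is_panel].reset_index(drop=True)
    labels = panel_labels.loc[panel["sample_id"]].to_numpy()
    if pc_pairs is None:
        pc_pairs = {
            ancestry: select_pc_pair(panel, labels, ancestry)
            for ancestry in pd.unique(labels)
        }
    else:
        pc_pairs = dict(pc_pairs)

    memberships = {}
    k_used = {}
    for ancestry, (pa, pb) in pc_pairs.items():
        if ancestry not in set(labels):
            continue
        cols = [f"pc{pa}", f"pc{pb}"]
        coords_panel = panel[cols].to_numpy()
        coords_study = study[cols].to_numpy()
        k = _select_k(coords_panel, labels, k_grid, cv_folds, seed)
        if pd.Series(labels).value_counts().get(ancestry, 0) < k:
            raise ValueError(f"panel class {ancestry} has fewer than k={k} samples")
        k_used[ancestry] = k
        memberships[ancestry] = _membership_fraction(
            coords_study, coords_panel, labels, ancestry, k
        )

    out = pd.DataFrame({"sample_id": study["sample_id"]})
    for ancestry, frac in memberships.items():
        out[f"membership_{ancestry}"] = frac
    mem = np.column_stack([memberships[a] for a in memberships])
    ancestries = list(memberships)
    above = mem > threshold
    n_above = above.sum(axis=1)
    label = np.where(
        n_above == 1,
        [ancestries[i] for i in above.argmax(axis=1)],
        AMBIGUOUS,
    ).astype(object)
    best = mem.max(axis=1)
    out["label"] = [
        gia_names.get(l, l) if l != AMBIGUOUS else AMBIGUOUS for l in label
    ]
    out["membership"] = best
    return GiaAssignment(table=out, k_per_ancestry=k_used)


def assign_subcontinental_gia(
    scores: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 0.90,
    n_pcs: int = 4,
    min_group: int = 20,
    group_name: str = "",
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    cv_folds: int = 10,
    seed: int = 0,
) -> GiaAssignment:
    """Subcontinental GIA within one continental group, on PCs 1..n_pcs.

    ``labels`` may come from the panel's subpopulations or from the study
    cohort's SIRE; label classes with N <= ``min_group`` are dropped from
    the label set. Samples below the membership threshold in every class
    are "Ambiguous <group>".
    """
    labels = labels.astype(str)
    counts = labels.value_counts()
    kept_classes = counts[counts > min_group].index
    if len(kept_classes) == 0:
        raise ValueError(f"no label class exceeds min_group={min_group}")
    labels = labels[labels.isin(kept_classes)]

    cols = [f"pc{i + 1}" for i in range(n_pcs)]
    is_labeled = scores["sample_id"].isin(labels.index).to_numpy()
    ref = scores[is_labeled].reset_index(drop=True)
    query = scores[~is_labeled].reset_index(drop=True)
    y = labels.loc[ref["sample_id"]].to_numpy()
    coords_ref = ref[cols].to_numpy()
    coords_query = query[cols].to_numpy()

    k = _select_k(coords_ref, y, k_grid, cv_folds, seed)
    out = pd.DataFrame({"sample_id": query["sample_id"]})
    mem = np.column_stack(
        [
            _membership_fraction(coords_query, coords_ref, y, cls, k)
            for cls in kept_classes
        ]
    )
    ambiguous_label = f"{AMBIGUOUS} {group_name}".strip()
    above = mem > threshold
    n_above = above.sum(axis=1)
    classes = list(kept_classes)
    out["label"] = np.where(
        n_above == 1,
        [classes[i] for i in above.argmax(axis=1)],
        ambiguous_label,
    ).astype(object)
    out["membership"] = mem.max(axis=1)
    for i, cls in enumerate(classes):
        out[f"membership_{cls}"] = mem[:, i]
    return GiaAssignment(table=out, k_per_ancestry={"all": k})


# ----------------------------------------------------------------------
# admixture EM
# ----------------------------------------------------------------------
@dataclass
class AdmixtureFit:
    Q: np.ndarray  # N x K, rows sum to 1
    F: np.ndarray  # K x M, in (0, 1)
    loglik: float
    loglik_trace: np.ndarray
    K: int
    converged: bool
    component_labels: list = field(default_factory=list)


def _admixture_loglik(g: np.ndarray, obs: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    p = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    ll = g * np.log(p) + (2.0 - g) * np.log1p(-p)
    return float(ll[obs].sum())


def fit_admixture(
    g: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_init: int = 3,
) -> AdmixtureFit:
    """Unsupervised admixture by EM on the binomial mixture likelihood.

    ``tol`` is the relative log-likelihood gain below which iteration stops.
    ``n_init`` random restarts (Dirichlet Q, Uniform F) are run and the best
    likelihood kept; restarts and every draw are controlled by ``seed``.
    Missing dosages contribute nothing to the likelihood or the updates.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    G = g.dosages.astype(np.float64)
    obs = g.observed_mask()
    G[~obs] = 0.0
    W = obs.astype(np.float64)
    n_obs_per_sample = np.maximum(W.sum(axis=1), 1.0)

    if K == 1:
        # degenerate mixture: closed form in one step
        p_hat = np.clip(g.allele1_freq(), 1e-6, 1 - 1e-6)
        Q = np.ones((g.n_samples, 1))
        F = p_hat[None, :]
        ll = _admixture_loglik(G, obs, Q, F)
        return AdmixtureFit(Q, F, ll, np.array([ll]), 1, True)

    rng = np.random.default_rng(seed)
    best: AdmixtureFit | None = None
    for _ in range(n_init):
        Q = rng.dirichlet(np.ones(K), size=g.n_samples)
        F = rng.uniform(0.05, 0.95, size=(K, g.n_variants))
        trace = []
        prev = -np.inf
        converged = False
        for _it in range(max_iter):
            P = np.clip(Q @ F, 1e-12, 1 - 1e-12)  # N x M
            Pc = np.clip(1.0 - P, 1e-12, 1.0)
            A_num = np.zeros_like(Q)  # per-sample expected allele-1 counts by k
            B_num = np.zeros_like(Q)
            F_num = np.zeros((K, g.n_variants))
            F_den = np.zeros((K, g.n_variants))
            for k in range(K):
                a = (Q[:, k : k + 1] * F[k]) / P  # responsibility, allele 1
                b = (Q[:, k : k + 1] * (1.0 - F[k])) / Pc  # allele 2
                ga = G * a * W
                gb = (2.0 - G) * b * W
                A_num[:, k] = ga.sum(axis=1)
                B_num[:, k] = gb.sum(axis=1)
                F_num[k] = ga.sum(axis=0)
                F_den[k] = ga.sum(axis=0) + gb.sum(axis=0)
            Q = (A_num + B_num) / (2.0 * n_obs_per_sample[:, None])
            Q = np.clip(Q, 1e-12, None)
            Q /= Q.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                F = np.where(F_den > 0, F_num / F_den, F)
            F = np.clip(F, 1e-6, 1 - 1e-6)
            ll = _admixture_loglik(G, obs, Q, F)
            trace.append(ll)
            if np.isfinite(prev) and ll - prev < tol * abs(ll):
                converged = True
                break
            prev = ll
        fit = AdmixtureFit(Q, F, trace[-1], np.array(trace), K, converged)
        if best is None or fit.loglik > best.loglik:
            best = fit
    if not best.converged:
        warnings.warn("admixture EM did not converge; returning best fit")
    return best


def align_components(
    fit_F_or_Q: np.ndarray, truth: np.ndarray, by: str = "columns"
) -> np.ndarray:
    """Best component permutation (Hungarian matching on correlation).

    Returns the permutation ``perm`` such that estimated component
    ``perm[k]`` corresponds to truth component ``k``. ``by="columns"``
    matches N x K matrices column-wise; ``by="rows"`` matches K x M
    frequency matrices row-wise.
    """
    from scipy.optimize import linear_sum_assignment

    est = fit_F_or_Q if by == "columns" else fit_F_or_Q.T
    tru = truth if by == "columns" else truth.T
    K = est.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            va, vb = tru[:, a], est[:, b]
            denom = va.std() * vb.std()
            corr = ((va - va.mean()) * (vb - vb.mean())).mean() / denom if denom > 0 else 0.0
            cost[a, b] = -corr
    _, perm = linear_sum_assignment(cost)
    return perm


def label_admixture_components(
    fit: AdmixtureFit,
    sire: pd.Series,
    rules: list[tuple[list[str], str]] | None = None,
) -> AdmixtureFit:
    """Name admixture components from SIRE majorities.

    ``rules`` is an ordered list of (sire groups, ancestry label); for each
    rule the component on which the named SIRE group(s) load most heavily
    (mean Q) gets the label. The defaults encode the K=4 convention:
    NH-White -> European, NH-AfAm -> African, NH-Asian -> East Asian, and
    HL-Other + HL-White -> Native American (the highest remaining loading).
    An exact tie leaves the component unlabeled with a warning.
    """
    if rules is None:
        rules = [
            (["NH-White"], "European"),
            (["NH-AfAm"], "African"),
            (["NH-Asian"], "East Asian"),
            (["HL-Other", "HL-White"], "Native American"),
        ]
    sire = sire.reset_index(drop=True)
    labels: list[str | None] = [None] * fit.K
    taken: set[int] = set()
    for groups, name in rules:
        mask = sire.isin(groups).to_numpy()
        if not mask.any():
            continue
        mean_q = fit.Q[mask].mean(axis=0)
        order = np.argsort(-mean_q)
        free = [k for k in order if k not in taken]
        if not free:
            continue
        top = free[0]
        ties = [k for k in free if np.isclose(mean_q[k], mean_q[top])]
        if len(ties) > 1:
            warnings.warn(f"tie between components {ties} for label {name!r}; withheld")
            continue
        labels[top] = name
        taken.add(top)
    fit.component_labels = labels
    return fit
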