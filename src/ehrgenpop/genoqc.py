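"""Variant/sample QC, kinship, relatedness pruning, LD pruning and allele
alignment against a reference panel.

Conventions
-----------
* All missingness filters are strict: a rate *greater than* the threshold
  removes the unit; a rate exactly at the threshold is retained.
* Strand-ambiguous means the allele pair is A/T or C/G (indistinguishable
  under a strand flip).
* Kinship is the KING-robust between-family estimator by default: for a
  pair (i, j) with i the member with fewer heterozygous calls over the
  co-observed variants,

      phi = ( N_het,het - 2 * N_opposite_hom ) / (2 * N_het(i))
            + 1/2 - ( N_het(i) + N_het(j) ) / (4 * N_het(i))

  which is exactly 0.5 for identical genotypes, ~0.25 for first-degree
  pairs and ~0 for unrelated pairs regardless of allele frequencies.
  An allele-frequency GRM estimator is available as ``method="grm"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, GenotypeMatrix

DEGREE2_CUTOFF = 0.0884  # second-degree kinship inclusion bound
DEGREE3_CUTOFF = 0.0442  # third-degree bound used for IBD relative filtering

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_ACGT = {"A", "C", "G", "T"}


@dataclass
class QcReport:
    """Counts of removed units per rule; removed + retained == input."""

    stage: str
    n_input: int
    n_retained: int
    removed: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_retained + sum(self.removed.values()) != self.n_input:
            raise ValueError("QcReport counts do not reconcile")

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage": self.stage,
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "removed": self.removed,
                "thresholds": self.thresholds,
            },
            indent=2,
        )


# ----------------------------------------------------------------------
# variant / sample filters
# ----------------------------------------------------------------------
def qc_variants(
    g: GenotypeMatrix,
    max_missing: float = 0.05,
    drop_strand_ambiguous: bool = True,
    drop_unmapped: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop unmapped, high-missingness and strand-ambiguous variants."""
    v = g.variants
    keep = np.ones(g.n_variants, dtype=bool)
    removed = {}

    if drop_unmapped:
        chrom = v["chrom"].astype(str)
        bp = pd.to_numeric(v["bp"], errors="coerce")
        unmapped = (
            chrom.isin(["0", "", "nan", "None"]).to_numpy()
            | bp.isna().to_numpy()
            | (bp.fillna(0) <= 0).to_numpy()
        )
        removed["unmapped"] = int((unmapped & keep).sum())
        keep &= ~unmapped

    miss = g.variant_missing_rate()
    high_miss = miss > max_missing
    removed["missingness"] = int((high_miss & keep).sum())
    keep &= ~high_miss

    if drop_strand_ambiguous:
        pairs = list(zip(v["allele1"].astype(str), v["allele2"].astype(str)))
        ambiguous = np.array([p in _AMBIGUOUS_PAIRS for p in pairs])
        removed["strand_ambiguous"] = int((ambiguous & keep).sum())
        keep &= ~ambiguous

    report = QcReport(
        stage="qc_variants",
        n_input=g.n_variants,
        n_retained=int(keep.sum()),
        removed=removed,
        thresholds={"max_missing": max_missing},
    )
    return g.subset_variants(keep), report


def qc_samples(
    g: GenotypeMatrix, max_missing: float = 0.05
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples whose call missingness exceeds ``max_missing`` (strict >)."""
    miss = g.sample_missing_rate()
    keep = miss <= max_missing
    report = QcReport(
        stage="qc_samples",
        n_input=g.n_samples,
        n_retained=int(keep.sum()),
        removed={"missingness": int((~keep).sum())},
        thresholds={"max_missing": max_missing},
    )
    return g.subset_samples(keep), report


def maf_filter(g: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep variants with MAF >= ``min_maf`` (computed on non-missing calls)."""
    maf = g.maf()
    keep = np.nan_to_num(maf, nan=-1.0) >= min_maf
    return g.subset_variants(keep)


def hwe_test(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant Hardy–Weinberg chi-square p-value (1 df, no continuity
    correction). Monomorphic variants return p = 1."""
    d = g.dosages
    obs = g.observed_mask()
    n_aa = ((d == 0) & obs).sum(axis=0).astype(float)
    n_ab = ((d == 1) & obs).sum(axis=0).astype(float)
    n_bb = ((d == 2) & obs).sum(axis=0).astype(float)
    n = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_bb + n_ab) / (2 * n)
    q = 1.0 - p
    e_aa, e_ab, e_bb = n * q**2, 2 * n * p * q, n * p**2
    chi2 = np.zeros(g.n_variants)
    for o, e in ((n_aa, e_aa), (n_ab, e_ab), (n_bb, e_bb)):
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(e > 0, (o - e) ** 2 / e, 0.0)
        chi2 += np.nan_to_num(term)
    pvals = stats.chi2.sf(chi2, df=1)
    mono = (p <= 0) | (p >= 1) | (n == 0)
    pvals[mono] = 1.0
    return pvals


def heterozygosity_outliers(g: GenotypeMatrix, n_sd: float = 3.0) -> list[str]:
    """Sample ids whose heterozygous-call fraction is outside mean +/- n_sd SD.

    Computed within one (GIA) group. With fewer than 3 samples, or zero
    spread, nothing is flagged.
    """
    if g.n_samples < 3:
        warnings.warn("fewer than 3 samples; no heterozygosity outliers flagged")
        return []
    obs = g.observed_mask()
    het = ((g.dosages == 1) & obs).sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
    mu, sd = het.mean(), het.std()
    if sd == 0 or not np.isfinite(n_sd):
        return []
    flagged = np.abs(het - mu) > n_sd * sd
    return list(g.samples["id"][flagged])


# ----------------------------------------------------------------------
# kinship & relatedness
# ----------------------------------------------------------------------
def estimate_kinship(g: GenotypeMatrix, method: str = "king") -> pd.DataFrame:
    """Pairwise kinship table (columns id1, id2, phi, n_snps).

    ``method="king"`` is the KING-robust between-family estimator;
    ``method="grm"`` is the allele-frequency-standardized GRM / 2.
    Pairs with no co-observed variants get phi = NaN.
    """
    if g.n_samples < 2:
        raise ValueError("kinship needs >= 2 samples")
    d = g.dosages
    obs = g.observed_mask().astype(np.float64)
    ids = g.samples["id"].to_numpy()
    n_co = obs @ obs.T

    if method == "king":
        het = ((d == 1) & (d != MISSING)).astype(np.float64)
        hom0 = (d == 0).astype(np.float64)
        hom2 = (d == 2).astype(np.float64)
        n_hh = het @ het.T  # both heterozygous
        n_opp = hom0 @ hom2.T + hom2 @ hom0.T  # opposite homozygotes
        het_i_co = het @ obs.T  # het count of i over sites observed in j
        n_min = np.minimum(het_i_co, het_i_co.T)
        n_max = np.maximum(het_i_co, het_i_co.T)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = (
                (n_hh - 2.0 * n_opp) / (2.0 * n_min)
                + 0.5
                - (n_min + n_max) / (4.0 * n_min)
            )
    elif method == "grm":
        p = g.allele1_freq()
        denom = np.sqrt(2.0 * p * (1.0 - p))
        x = np.where(obs > 0, d, 0).astype(float) - 2.0 * p * obs
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(denom > 0, x / denom, 0.0)
        m_eff = obs @ obs.T
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = (x @ x.T) / m_eff / 2.0
    else:
        raise ValueError(f"unknown kinship method {method!r}")

    iu, ju = np.triu_indices(g.n_samples, k=1)
    phi_pairs = phi[iu, ju]
    degenerate = n_co[iu, ju] == 0
    phi_pairs = np.where(degenerate, np.nan, phi_pairs)
    return pd.DataFrame(
        {
            "id1": ids[iu],
            "id2": ids[ju],
            "phi": phi_pairs,
            "n_snps": n_co[iu, ju].astype(int),
        }
    )


def remove_duplicates(
    g: GenotypeMatrix,
    kin: pd.DataFrame,
    dup_threshold: float = 0.354,
    drop_policy: str = "keep_cleaner",
) -> GenotypeMatrix:
    """Resolve duplicate/MZ pairs (phi >= ``dup_threshold``), one survivor per
    connected group of mutual duplicates.

    ``drop_policy="keep_cleaner"`` keeps the member with the lowest missing
    rate; ``"drop_cleaner"`` reproduces the literal alternative of removing
    the lowest-missingness member. Ties break toward the earlier sample id.
    """
    if drop_policy not in ("keep_cleaner", "drop_cleaner"):
        raise ValueError("drop_policy must be 'keep_cleaner' or 'drop_cleaner'")
    miss = dict(zip(g.samples["id"], g.sample_missing_rate()))
    dup = kin[kin["phi"] >= dup_threshold]
    # transitive grouping: union-find over duplicate edges
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(dup["id1"], dup["id2"]):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    clusters: dict[str, list[str]] = {}
    for x in parent:
        clusters.setdefault(find(x), []).append(x)

    drop: set[str] = set()
    for members in clusters.values():
        members.sort(key=lambda s: (miss[s], s))  # cleanest first
        survivor = members[0] if drop_policy == "keep_cleaner" else members[-1]
        drop.update(m for m in members if m != survivor)
    keep = ~g.samples["id"].isin(drop).to_numpy()
    return g.subset_samples(keep)


def unrelated_set(kin: pd.DataFrame, threshold: float = DEGREE2_CUTOFF) -> set[str]:
    """Greedy maximal set with no pair at phi >= ``threshold``.

    Iteratively removes the node with the most remaining related partners
    (ties broken by sample id order), which is optimal on stars and small
    graphs and deterministic everywhere.
    """
    related = kin[kin["phi"] >= threshold]
    nodes = set(kin["id1"]) | set(kin["id2"])
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for a, b in zip(related["id1"], related["id2"]):
        adj[a].add(b)
        adj[b].add(a)
    active = set(nodes)
    while True:
        degrees = {n: len(adj[n] & active) for n in active}
        worst = max(degrees.values(), default=0)
        if worst == 0:
            return active
        candidates = sorted(n for n, d in degrees.items() if d == worst)
        active.discard(candidates[0])


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------
def _corr_matrix(x: np.ndarray) -> np.ndarray:
    """Pearson correlation of columns; zero-variance columns give r = 0."""
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xs = np.where(sd > 0, xc / sd, 0.0)
    return (xs.T @ xs) / x.shape[0]


def ld_prune_pairwise(
    g: GenotypeMatrix,
    window_variants: int = 100,
    step: int = 5,
    r2_max: float = 0.1,
) -> list[str]:
    """Sliding-window pairwise LD pruning (the ``--indep-pairwise`` rule).

    Within each window of ``window_variants`` consecutive variants (per
    chromosome), whenever a retained pair has squared dosage correlation
    > ``r2_max`` the later variant (higher bp) is removed; the window then
    advances by ``step``. Missing calls are mean-imputed for r^2.
    """
    x = g.mean_imputed()
    order = np.lexsort((g.variants["bp"].to_numpy(), g.variants["chrom"].to_numpy()))
    removed = np.zeros(g.n_variants, dtype=bool)
    chroms = g.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = order[chroms[order] == chrom]
        start = 0
        while start < len(idx):
            window = idx[start : start + window_variants]
            active = [j for j in window if not removed[j]]
            if len(active) > 1:
                r2 = _corr_matrix(x[:, active]) ** 2
                for a in range(len(active)):
                    if removed[active[a]]:
                        continue
                    for b in range(a + 1, len(active)):
                        if removed[active[b]]:
                            continue
                        if r2[a, b] > r2_max:
                            removed[active[b]] = True
            if start + window_variants >= len(idx):
                break
            start += step
    return list(g.variants["id"][~removed])


def ld_prune_vif(
    g: GenotypeMatrix,
    window_variants: int = 200,
    step: int = 5,
    vif_max: float = 1.15,
    ridge: float = 1e-8,
) -> list[str]:
    """Sliding-window variance-inflation-factor pruning (the ``--indep`` rule).

    Within each window, iteratively remove the variant with the largest
    VIF = 1/(1 - R^2) from regressing its dosage on the other variants in
    the window, until all VIFs are <= ``vif_max``. A ridge epsilon keeps the
    within-window correlation matrix invertible when variants are collinear.
    """
    x = g.mean_imputed()
    order = np.lexsort((g.variants["bp"].to_numpy(), g.variants["chrom"].to_numpy()))
    removed = np.zeros(g.n_variants, dtype=bool)
    chroms = g.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = order[chroms[order] == chrom]
        start = 0
        while start < len(idx):
            window = idx[start : start + window_variants]
            while True:
                active = [j for j in window if not removed[j]]
                if len(active) < 2:
                    break
                r = _corr_matrix(x[:, active])
                r[np.diag_indices_from(r)] += ridge
                try:
                    vifs = np.diag(np.linalg.inv(r))
                except np.linalg.LinAlgError:
                    vifs = np.diag(np.linalg.pinv(r))
                # ties (e.g. exact copies) drop the later variant
                worst = int(np.flatnonzero(vifs >= vifs.max() - 1e-9)[-1])
                if vifs[worst] <= vif_max:
                    break
                removed[active[worst]] = True
            if start + window_variants >= len(idx):
                break
            start += step
    return list(g.variants["id"][~removed])


def prune_bp_spacing(g: GenotypeMatrix, min_bp: int = 2000) -> list[str]:
    """Greedy left-to-right thinning keeping variants >= ``min_bp`` apart
    within each chromosome (the ``--bp-space`` rule)."""
    keep_ids = []
    v = g.variants.sort_values(["chrom", "bp"], kind="stable")
    for _, sub in v.groupby("chrom", sort=False):
        last = None
        for row in sub.itertuples(index=False):
            if last is None or row.bp - last >= min_bp:
                keep_ids.append(row.id)
                last = row.bp
    id_order = {vid: i for i, vid in enumerate(g.variants["id"])}
    return sorted(keep_ids, key=id_order.get)


# ----------------------------------------------------------------------
# reference alignment
# ----------------------------------------------------------------------
def align_to_reference(
    study: GenotypeMatrix, panel: GenotypeMatrix
) -> GenotypeMatrix:
    """Merge study and panel samples over shared (chrom, bp) variants.

    Same allele pair -> keep; swapped allele1/allele2 -> study dosage
    recoded g -> 2 - g; non-ACGT alleles or irreconcilable allele sets ->
    variant dropped. Strand flips are not attempted (strand-ambiguous
    variants are expected to have been removed upstream).
    """
    s = study.variants.assign(pos=range(study.n_variants))
    p = panel.variants.assign(pos=range(panel.n_variants))
    merged = s.merge(p, on=["chrom", "bp"], suffixes=("_s", "_p"))
    if merged.empty:
        raise ValueError("no overlapping variants between study and panel")

    keep_s, keep_p, flip = [], [], []
    for row in merged.itertuples(index=False):
        alleles = {row.allele1_s, row.allele2_s, row.allele1_p, row.allele2_p}
        if not alleles <= _ACGT:
            continue
        if (row.allele1_s, row.allele2_s) == (row.allele1_p, row.allele2_p):
            keep_s.append(row.pos_s)
            keep_p.append(row.pos_p)
            flip.append(False)
        elif (row.allele1_s, row.allele2_s) == (row.allele2_p, row.allele1_p):
            keep_s.append(row.pos_s)
            keep_p.append(row.pos_p)
            flip.append(True)
        # anything else: allele mismatch, drop
    if not keep_s:
        raise ValueError("no reconcilable variants between study and panel")

    ds = study.dosages[:, keep_s].copy()
    flip = np.array(flip)
    if flip.any():
        cols = ds[:, flip]
        obs = cols != MISSING
        cols[obs] = 2 - cols[obs]
        ds[:, flip] = cols
    dp = panel.dosages[:, keep_p].copy()

    variants = panel.variants.iloc[keep_p].reset_index(drop=True)
    samples = pd.concat([study.samples, panel.samples], ignore_index=True)
    if samples["id"].duplicated().any():
        raise ValueError("sample ids collide between study and panel")
    return GenotypeMatrix(np.vstack([ds, dp]), variants, samples)


def mendel_filter(g: GenotypeMatrix, pedigree: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Mendel-error filtering; a no-op with a warning when no pedigree is
    supplied (synthetic cohorts are founders-only)."""
    if pedigree is None or pedigree.empty:
        warnings.warn("no pedigree supplied; Mendel-error filtering skipped")
        return g
    raise NotImplementedError("pedigree-based Mendel filtering is not implemented")
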