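"""Synthetic reference panels, admixed cohorts, EHR encounters and IBD segments.

The generator provides every input the downstream stages assume, with known
ground truth so recovery can be measured:

* K ancestral populations whose allele frequencies diverge from a shared
  ancestral frequency by the Balding–Nichols construction (Beta-distributed
  with dispersion set by a per-population Fst);
* admixed study cohorts with Dirichlet ancestry proportions, genotypes drawn
  binomially from the individual's mixed allele frequency, and SIRE/language
  labels that track the dominant ancestry up to a configurable noise rate;
* encounter-level ICD tables generated from a logistic disease model with
  ancestry-, sex-, age- (and optionally SNP-) dependent case probabilities;
* community-structured pairwise IBD sharing.

Variants are independent given ancestry — there is no LD, phasing or
recombination map. That is deliberate: every downstream method here
(PCA, KNN ancestry assignment, admixture EM, logistic scans) operates on
unlinked sites, and LD pruning reduces real data toward this regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

_BASES = np.array(list("ACGT"))

# encounter types; the first four count as "visit" encounters downstream
VISIT_TYPES = ("appointment", "office", "hospital", "procedure")
NONVISIT_TYPES = ("telehealth_message", "phone", "lab", "note")


# ----------------------------------------------------------------------
# population model
# ----------------------------------------------------------------------
@dataclass
class PopulationModel:
    """K ancestral populations with Balding–Nichols divergence.

    ``pop_freqs`` (K x M) are drawn once at construction from
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral frequency ``p``,
    so ``E[p_k] = p`` and ``Var[p_k] = F p (1-p)``.
    """

    K: int
    M: int
    fst_per_pop: np.ndarray
    ancestral_freq: np.ndarray
    pop_freqs: np.ndarray
    variants: pd.DataFrame

    @classmethod
    def simulate(
        cls,
        K: int,
        M: int,
        fst: float | list[float] = 0.1,
        seed: int = 0,
        ancestral_freq_range: tuple[float, float] = (0.05, 0.95),
        n_chrom: int = 22,
    ) -> "PopulationModel":
        fst_arr = np.broadcast_to(np.asarray(fst, dtype=float), (K,)).copy()
        if np.any(fst_arr <= 0) or np.any(fst_arr >= 1):
            raise ValueError("fst values must lie strictly in (0, 1)")
        if K < 1:
            raise ValueError("K must be >= 1")
        lo, hi = ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be within (0, 1)")
        rng = np.random.default_rng(seed)
        p = rng.uniform(lo, hi, size=M)
        pop_freqs = np.empty((K, M))
        for k in range(K):
            F = fst_arr[k]
            a = p * (1.0 - F) / F
            b = (1.0 - p) * (1.0 - F) / F
            pop_freqs[k] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        variants = _make_variant_table(M, n_chrom, rng)
        return cls(K, M, fst_arr, p, pop_freqs, variants)


def _make_variant_table(M: int, n_chrom: int, rng: np.random.Generator) -> pd.DataFrame:
    chrom = np.sort(rng.integers(1, n_chrom + 1, size=M))
    bp = np.empty(M, dtype=np.int64)
    for c in np.unique(chrom):
        mask = chrom == c
        gaps = rng.integers(500, 20_000, size=mask.sum())
        bp[mask] = np.cumsum(gaps)
    pair_idx = rng.integers(0, 4, size=M)
    allele1 = _BASES[pair_idx]
    # choose a non-complementary partner so simulated variants are never
    # strand-ambiguous by construction (QC tests inject those explicitly)
    partner = {"A": ["C", "G"], "C": ["A", "T"], "G": ["A", "T"], "T": ["C", "G"]}
    allele2 = np.array(
        [partner[a][i % 2] for i, a in enumerate(allele1)], dtype="<U1"
    )
    return pd.DataFrame(
        {
            "chrom": chrom.astype(str),
            "bp": bp,
            "id": [f"snp{i}" for i in range(M)],
            "allele1": allele1,
            "allele2": allele2,
        }
    )


# ----------------------------------------------------------------------
# cohort specification
# ----------------------------------------------------------------------
@dataclass
class GroupSpec:
    """One labeled cohort stratum: size, Dirichlet ancestry prior, labels."""

    name: str
    n: int
    dirichlet_alpha: np.ndarray
    sire: str
    language: str = "English"


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    label_noise_rate: float = 0.0
    age_range: tuple[float, float] = (18.0, 90.0)
    female_fraction: float = 0.5
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("CohortSpec requires at least one group")
        if not 0.0 <= self.label_noise_rate <= 1.0:
            raise ValueError("label_noise_rate must lie in [0, 1]")
        for g in self.groups:
            g.dirichlet_alpha = np.asarray(g.dirichlet_alpha, dtype=float)
            if np.any(g.dirichlet_alpha <= 0):
                raise ValueError(f"group {g.name}: dirichlet_alpha must be > 0")


@dataclass
class TruthTable:
    """Ground truth for recovery tests."""

    sample_id: pd.Series
    q: np.ndarray  # N x K true admixture proportions
    population: np.ndarray  # dominant ancestral component per sample
    community: np.ndarray  # group index, used as planted IBD community
    case_prob: dict = field(default_factory=dict)  # phecode -> N-vector


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------
def simulate_reference_panel(
    model: PopulationModel,
    n_per_pop: int,
    seed: int = 0,
    pop_names: list[str] | None = None,
) -> GenotypeMatrix:
    """Draw a labeled reference panel: Binomial(2, p_k) genotypes per population."""
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    if pop_names is None:
        pop_names = [f"POP{k}" for k in range(model.K)]
    if len(pop_names) != model.K:
        raise ValueError("pop_names length must equal K")
    blocks, labels = [], []
    for k in range(model.K):
        blocks.append(
            rng.binomial(2, model.pop_freqs[k], size=(n_per_pop, model.M)).astype(
                np.int8
            )
        )
        labels.extend([pop_names[k]] * n_per_pop)
    samples = pd.DataFrame(
        {
            "id": [f"ref{k}_{i}" for k in range(model.K) for i in range(n_per_pop)],
            "population": labels,
        }
    )
    return GenotypeMatrix(np.vstack(blocks), model.variants.copy(), samples)


def simulate_admixed_cohort(
    model: PopulationModel, spec: CohortSpec, seed: int | None = None
) -> tuple[GenotypeMatrix, TruthTable, pd.DataFrame]:
    """Dirichlet-admixed cohort with demographics.

    Genotypes: ``g_ij ~ Binomial(2, sum_k q_ik f_kj)``. SIRE and language
    come from the sample's group; with probability ``label_noise_rate`` the
    SIRE is replaced by one drawn from the other groups.
    """
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng(seed)
    K = model.K
    rows_q, rows_g, ids, groups, sires, langs, comm = [], [], [], [], [], [], []
    sire_pool = [g.sire for g in spec.groups]
    for gi, grp in enumerate(spec.groups):
        if len(grp.dirichlet_alpha) != K:
            raise ValueError(
                f"group {grp.name}: alpha length {len(grp.dirichlet_alpha)} != K={K}"
            )
        q = rng.dirichlet(grp.dirichlet_alpha, size=grp.n)
        p_ind = q @ model.pop_freqs  # n x M mixed allele frequencies
        g = rng.binomial(2, p_ind).astype(np.int8)
        rows_q.append(q)
        rows_g.append(g)
        ids.extend([f"{grp.name}_{i}" for i in range(grp.n)])
        groups.extend([grp.name] * grp.n)
        sires.extend([grp.sire] * grp.n)
        langs.extend([grp.language] * grp.n)
        comm.extend([gi] * grp.n)
    q_all = np.vstack(rows_q)
    g_all = np.vstack(rows_g)
    n_total = len(ids)

    sires = np.array(sires, dtype=object)
    if spec.label_noise_rate > 0 and len(sire_pool) > 1:
        flip = rng.random(n_total) < spec.label_noise_rate
        for i in np.flatnonzero(flip):
            others = [s for s in sire_pool if s != sires[i]]
            sires[i] = others[rng.integers(len(others))]

    if spec.missing_rate > 0:
        miss = rng.random(g_all.shape) < spec.missing_rate
        g_all[miss] = MISSING

    age = rng.uniform(*spec.age_range, size=n_total)
    sex = np.where(rng.random(n_total) < spec.female_fraction, "F", "M")
    demographics = pd.DataFrame(
        {
            "person_id": ids,
            "age": np.round(age, 1),
            "sex": sex,
            "sire": sires,
            "language": langs,
            "group": groups,
        }
    )
    samples = pd.DataFrame({"id": ids, "group": groups})
    geno = GenotypeMatrix(g_all, model.variants.copy(), samples)
    truth = TruthTable(
        sample_id=pd.Series(ids, name="sample_id"),
        q=q_all,
        population=q_all.argmax(axis=1),
        community=np.array(comm),
    )
    return geno, truth, demographics


# ----------------------------------------------------------------------
# phenotypes / encounters
# ----------------------------------------------------------------------
@dataclass
class PhecodeEffect:
    """Disease model for one phecode: logit(P(case)) is linear in covariates."""

    phecode: str
    baseline: float  # beta0, log-odds at reference covariates
    group_effects: dict = field(default_factory=dict)  # group/GIA name -> beta1
    sex_effect: float = 0.0  # beta2, for female vs male
    age_effect: float = 0.0  # beta3, per year centered at 54
    sire_effects: dict = field(default_factory=dict)  # beta4 per SIRE
    causal_variants: dict = field(default_factory=dict)  # variant id -> per-allele beta
    sex_specific: str = "none"  # none | male | female
    mean_occurrences: float = 2.0  # mean phecode occurrences per case


@dataclass
class PhenotypeModel:
    phecodes: list[PhecodeEffect]

    def validate(self, geno: GenotypeMatrix | None) -> None:
        known = set(geno.variants["id"]) if geno is not None else set()
        for eff in self.phecodes:
            unknown = set(eff.causal_variants) - known
            if unknown:
                raise ValueError(
                    f"phecode {eff.phecode} references unknown variants {unknown}"
                )


def make_ontology(phecodes: list[PhecodeEffect], icd_per_phecode: int = 2) -> pd.DataFrame:
    """Miniature ICD->phecode map: synthetic ICD codes, one phecode each."""
    rows = []
    for eff in phecodes:
        for v in range(icd_per_phecode):
            version = "ICD10" if v % 2 == 0 else "ICD9"
            rows.append(
                {
                    "icd_code": f"X{eff.phecode}.{v}",
                    "icd_version": version,
                    "phecode": eff.phecode,
                    "phecode_label": f"synthetic phenotype {eff.phecode}",
                    "sex_specific": eff.sex_specific,
                }
            )
    return pd.DataFrame(rows)


def case_probabilities(
    model: PhenotypeModel,
    demographics: pd.DataFrame,
    geno: GenotypeMatrix | None = None,
    group_col: str = "group",
) -> dict[str, np.ndarray]:
    """Per-phecode case probability for every person, from the logistic model."""
    if geno is not None:
        model.validate(geno)
        id_to_col = {v: j for j, v in enumerate(geno.variants["id"])}
        order = (
            demographics["person_id"]
            .map({s: i for i, s in enumerate(geno.samples["id"])})
            .to_numpy()
        )
    out = {}
    female = (demographics["sex"] == "F").to_numpy(float)
    age_c = demographics["age"].to_numpy(float) - 54.0
    for eff in model.phecodes:
        logit = np.full(len(demographics), eff.baseline, dtype=float)
        for grp, beta in eff.group_effects.items():
            logit += beta * (demographics[group_col] == grp).to_numpy(float)
        for sire, beta in eff.sire_effects.items():
            logit += beta * (demographics["sire"] == sire).to_numpy(float)
        logit += eff.sex_effect * female + eff.age_effect * age_c
        for vid, beta in eff.causal_variants.items():
            dos = geno.dosages[order, id_to_col[vid]].astype(float)
            dos[dos == MISSING] = 0.0
            logit += beta * dos
        prob = 1.0 / (1.0 + np.exp(-logit))
        if eff.sex_specific == "male":
            prob = np.where(female == 1.0, 0.0, prob)
        elif eff.sex_specific == "female":
            prob = np.where(female == 1.0, prob, 0.0)
        out[eff.phecode] = prob
    return out


def simulate_encounters(
    truth: TruthTable,
    model: PhenotypeModel,
    ontology: pd.DataFrame,
    demographics: pd.DataFrame,
    seed: int = 0,
    geno: GenotypeMatrix | None = None,
    group_col: str = "group",
    visit_fraction: float = 0.7,
) -> pd.DataFrame:
    """Encounter-level ICD table.

    Case status per (person, phecode) is Bernoulli in the logistic
    probability; each case receives >= 1 occurrence, every occurrence is a
    distinct encounter carrying one mapped ICD code, and encounter types mix
    visit-like and message-like channels. Controls receive no encounter for
    that phecode, so downstream case definitions are exact by construction.
    """
    rng = np.random.default_rng(seed)
    probs = case_probabilities(model, demographics, geno=geno, group_col=group_col)
    truth.case_prob = probs
    icd_by_phecode = {
        ph: sub[["icd_code", "icd_version"]].to_records(index=False)
        for ph, sub in ontology.groupby("phecode")
    }
    persons = demographics["person_id"].to_numpy()
    rows = []
    enc_counter = 0
    for eff in model.phecodes:
        prob = probs[eff.phecode]
        is_case = rng.random(len(persons)) < prob
        icds = icd_by_phecode[eff.phecode]
        n_occ_all = 1 + rng.poisson(max(eff.mean_occurrences - 1.0, 0.0), size=len(persons))
        for i in np.flatnonzero(is_case):
            for _ in range(n_occ_all[i]):
                enc_counter += 1
                visit = rng.random() < visit_fraction
                etype = (
                    VISIT_TYPES[rng.integers(len(VISIT_TYPES))]
                    if visit
                    else NONVISIT_TYPES[rng.integers(len(NONVISIT_TYPES))]
                )
                icd = icds[rng.integers(len(icds))]
                rows.append(
                    {
                        "person_id": persons[i],
                        "encounter_id": f"enc{enc_counter}",
                        "date": f"2021-{rng.integers(1, 13):02d}-{rng.integers(1, 29):02d}",
                        "encounter_type": etype,
                        "icd_code": icd[0],
                        "icd_version": icd[1],
                    }
                )
    columns = ["person_id", "encounter_id", "date", "encounter_type", "icd_code", "icd_version"]
    return pd.DataFrame(rows, columns=columns)


# ----------------------------------------------------------------------
# IBD segments
# ----------------------------------------------------------------------
def simulate_ibd_segments(
    truth: TruthTable,
    within_rate: float = 2.0,
    between_rate: float = 0.05,
    seed: int = 0,
    mean_cm: float = 8.0,
    min_cm: float = 3.0,
    n_chrom: int = 22,
) -> pd.DataFrame:
    """Community-structured pairwise IBD segment table.

    For each unordered pair the number of shared segments is Poisson with
    rate ``within_rate`` inside the same planted community and
    ``between_rate`` across communities; lengths are shifted-exponential
    (always positive). Columns: id1, id2, chrom, start_bp, end_bp, cm.
    """
    if not within_rate > between_rate >= 0:
        raise ValueError("require within_rate > between_rate >= 0")
    rng = np.random.default_rng(seed)
    ids = truth.sample_id.to_numpy()
    comm = truth.community
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    same = comm[iu] == comm[ju]
    rates = np.where(same, within_rate, between_rate)
    n_seg = rng.poisson(rates)
    rows = []
    for idx in np.flatnonzero(n_seg):
        for _ in range(n_seg[idx]):
            cm = min_cm + rng.exponential(mean_cm - min_cm)
            chrom = rng.integers(1, n_chrom + 1)
            start = rng.integers(1, 200_000_000)
            end = start + int(cm * 1_000_000)
            rows.append(
                {
                    "id1": ids[iu[idx]],
                    "id2": ids[ju[idx]],
                    "chrom": str(chrom),
                    "start_bp": start,
                    "end_bp": end,
                    "cm": round(cm, 4),
                }
            )
    columns = ["id1", "id2", "chrom", "start_bp", "end_bp", "cm"]
    return pd.DataFrame(rows, columns=columns)
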