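"""End-to-end orchestration from one configuration.

``run_all`` executes synthetic-data generation (or ingestion of user TSV/
PLINK inputs via the same file contracts), genotype QC, ancestry inference,
IBD communities, phecode construction and the association scans, writing
every stage output as a plain file plus a JSON manifest capturing the
resolved configuration, its hash and the seed. Because each stage reads and
writes files with documented schemas, any stage can be replaced by external
tools' outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, assoc, genoqc, ibdnet, phenotypes, synthdata
from .matrix import GenotypeMatrix

log = logging.getLogger("ehrgenpop")


@dataclass
class RunConfig:
    """All thresholds in one place; defaults are the pipeline's canonical
    operating points (kinship 0.0884/0.0442, membership 0.50/0.90, MAF grid,
    HWE p per context, k grid {5,10,15,20}, K grid {4,5,6}, alpha 0.05,
    genome-wide 5e-8)."""

    seed: int = 0
    out_dir: str = "run"
    # synthetic cohort
    n_pops: int = 4
    n_variants: int = 4000
    fst: float = 0.12
    n_per_ref_pop: int = 150
    group_sizes: tuple = (400, 250, 250, 150)
    dirichlet_concentration: float = 30.0
    label_noise_rate: float = 0.05
    n_phecodes: int = 12
    ibd_within_rate: float = 2.0
    ibd_between_rate: float = 0.05
    # QC
    max_variant_missing: float = 0.05
    max_sample_missing: float = 0.05
    dup_threshold: float = 0.354
    kinship_degree2: float = genoqc.DEGREE2_CUTOFF
    kinship_degree3: float = genoqc.DEGREE3_CUTOFF
    # ancestry prep
    pca_maf: float = 0.15
    pca_hwe_p: float = 0.001
    vif_window: int = 200
    vif_step: int = 5
    vif_max: float = 1.15
    pairwise_window: int = 100
    pairwise_step: int = 5
    pairwise_r2: float = 0.1
    n_pc: int = 10
    membership_continental: float = 0.50
    membership_subcontinental: float = 0.90
    knn_k_grid: tuple = (5, 10, 15, 20)
    # admixture prep
    admix_maf: float = 0.05
    admix_bp_space: int = 2000
    admix_K: int = 4
    admix_K_grid: tuple = (4, 5, 6)
    admix_max_iter: int = 300
    admix_n_init: int = 2
    # phenotypes / association
    min_cases_gwas: int = 50
    min_cases_subcontinental: int = 20
    min_cases_admixture: int = 10
    alpha: float = 0.05
    genome_wide_p: float = 5e-8
    hwe_p_gwas: float = 1e-12
    hwe_p_ibd: float = 1e-10
    gwas_maf: float = 0.01
    het_outlier_sd: float = 3.0
    # stage toggles
    stages: tuple = ("synth", "qc", "ancestry", "ibd", "phecodes", "assoc")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_phenotype_model(
    config: RunConfig, group_names: list[str]
) -> synthdata.PhenotypeModel:
    """Demo disease model: one planted GIA effect, one sex-specific phecode,
    the rest null with varying baselines."""
    rng = np.random.default_rng(config.seed + 17)
    effects = []
    for i in range(config.n_phecodes):
        base = float(rng.uniform(-2.5, -1.2))
        eff = synthdata.PhecodeEffect(phecode=f"{100 + i}.0", baseline=base)
        if i == 0:  # planted ancestry effect on the first group
            eff.group_effects = {group_names[0]: float(np.log(2.0))}
        if i == 1:
            eff.sex_specific = "female"
        if i == 2:
            eff.sex_effect = 0.4
            eff.age_effect = 0.01
        effects.append(eff)
    return synthdata.PhenotypeModel(effects)


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def run_all(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run %s: seed=%d stages=%s", config.config_hash(), config.seed, config.stages)
    rng_seed = config.seed
    artifacts: dict[str, str] = {}
    stages = set(config.stages)

    # ---------------- synth ----------------
    if "synth" not in stages:
        raise ValueError("run_all currently seeds every run from the synth stage")
    model = synthdata.PopulationModel.simulate(
        K=config.n_pops, M=config.n_variants, fst=config.fst, seed=rng_seed
    )
    pop_names = ["EUR", "AFR", "EAS", "AMR", "SAS"][: config.n_pops]
    panel = synthdata.simulate_reference_panel(
        model, config.n_per_ref_pop, seed=rng_seed + 1, pop_names=pop_names
    )
    sires = ["NH-White", "NH-AfAm", "NH-Asian", "HL-Other", "SA"][: config.n_pops]
    langs = ["English", "English", "Mandarin", "Spanish", "Hindi"][: config.n_pops]
    groups = []
    for gi, n in enumerate(config.group_sizes):
        alpha = np.full(config.n_pops, 0.35)
        alpha[gi % config.n_pops] = config.dirichlet_concentration
        groups.append(
            synthdata.GroupSpec(
                name=f"G{gi}",
                n=int(n),
                dirichlet_alpha=alpha,
                sire=sires[gi % config.n_pops],
                language=langs[gi % config.n_pops],
            )
        )
    spec = synthdata.CohortSpec(groups=groups, label_noise_rate=config.label_noise_rate)
    study, truth, demo = synthdata.simulate_admixed_cohort(model, spec, seed=rng_seed + 2)
    pheno_model = default_phenotype_model(config, [g.name for g in groups])
    ontology = synthdata.make_ontology(pheno_model.phecodes)
    encounters = synthdata.simulate_encounters(
        truth, pheno_model, ontology, demo, seed=rng_seed + 3, geno=study
    )
    segments = synthdata.simulate_ibd_segments(
        truth,
        within_rate=config.ibd_within_rate,
        between_rate=config.ibd_between_rate,
        seed=rng_seed + 4,
    )
    _write(demo, out / "demographics.tsv")
    _write(encounters, out / "encounters.tsv")
    _write(ontology, out / "ontology.tsv")
    _write(segments, out / "ibd_segments.tsv")
    artifacts["demographics"] = "demographics.tsv"
    artifacts["encounters"] = "encounters.tsv"

    # ---------------- qc ----------------
    if "qc" in stages:
        study_qc, vrep = genoqc.qc_variants(study, max_missing=config.max_variant_missing)
        study_qc, srep = genoqc.qc_samples(study_qc, max_missing=config.max_sample_missing)
        kin = genoqc.estimate_kinship(study_qc)
        study_qc = genoqc.remove_duplicates(study_qc, kin, dup_threshold=config.dup_threshold)
        unrelated = genoqc.unrelated_set(kin, threshold=config.kinship_degree2)
        _write(kin, out / "kinship.tsv")
        (out / "qc_report.json").write_text(
            json.dumps(
                {"variants": json.loads(vrep.to_json()), "samples": json.loads(srep.to_json()),
                 "n_unrelated": len(unrelated)},
                indent=2,
            )
        )
        artifacts["kinship"] = "kinship.tsv"
    else:
        study_qc, kin = study, None

    # ---------------- ancestry ----------------
    scores = gia = admix_fit = None
    if "ancestry" in stages:
        merged = genoqc.align_to_reference(study_qc, panel)
        merged = genoqc.maf_filter(merged, config.pca_maf)
        hwe_p = genoqc.hwe_test(merged)
        merged = merged.subset_variants(hwe_p >= config.pca_hwe_p)
        keep = genoqc.ld_prune_vif(
            merged, config.vif_window, config.vif_step, config.vif_max
        )
        merged = merged.keep_variant_ids(keep)
        keep = genoqc.ld_prune_pairwise(
            merged, config.pairwise_window, config.pairwise_step, config.pairwise_r2
        )
        merged = merged.keep_variant_ids(keep)
        _, scores = ancestry.fit_pca(merged, n_pc=min(config.n_pc, merged.n_samples - 1))
        panel_labels = panel.samples.set_index("id")["population"]
        pc_pairs = {
            p: ancestry.DEFAULT_CONTINENTAL_PCS.get(p, (1, 2)) for p in pop_names
        }
        gia = ancestry.assign_continental_gia(
            scores,
            panel_labels,
            threshold=config.membership_continental,
            pc_pairs=pc_pairs,
            k_grid=config.knn_k_grid,
            seed=rng_seed,
        )
        _write(scores, out / "pca_scores.tsv")
        _write(gia.table, out / "gia_assignments.tsv")
        artifacts["gia"] = "gia_assignments.tsv"

        admix_g = genoqc.maf_filter(study_qc, config.admix_maf)
        keep = genoqc.prune_bp_spacing(admix_g, config.admix_bp_space)
        admix_g = admix_g.keep_variant_ids(keep)
        admix_fit = ancestry.fit_admixture(
            admix_g,
            K=config.admix_K,
            seed=rng_seed,
            max_iter=config.admix_max_iter,
            n_init=config.admix_n_init,
        )
        sire_series = demo.set_index("person_id")["sire"].loc[admix_g.samples["id"]]
        admix_fit = ancestry.label_admixture_components(admix_fit, sire_series)
        qdf = pd.DataFrame(
            admix_fit.Q,
            columns=[f"Q{k}" for k in range(config.admix_K)],
        )
        qdf.insert(0, "sample_id", admix_g.samples["id"].to_numpy())
        _write(qdf, out / "admixture_Q.tsv")
        artifacts["admixture_Q"] = "admixture_Q.tsv"

    # ---------------- ibd ----------------
    if "ibd" in stages:
        edges = ibdnet.total_pairwise_ibd(segments)
        if kin is not None:
            edges = ibdnet.filter_relatives(edges, kin, phi_cutoff=config.kinship_degree3)
        comms = ibdnet.detect_communities(edges, seed=rng_seed)
        _write(
            comms.membership.rename("community_id").rename_axis("sample_id").reset_index(),
            out / "ibd_communities.tsv",
        )
        artifacts["ibd_communities"] = "ibd_communities.tsv"

    # ---------------- phecodes ----------------
    statuses = None
    if "phecodes" in stages:
        persons = list(demo["person_id"])
        counts = phenotypes.count_occurrences(encounters, ontology, persons, scope="all")
        statuses = phenotypes.define_cases(counts)
        _write(statuses, out / "phecode_matrix.tsv")
        artifacts["phecodes"] = "phecode_matrix.tsv"

    # ---------------- assoc ----------------
    if "assoc" in stages:
        if statuses is None or gia is None:
            raise ValueError("assoc stage requires phecodes and ancestry outputs")
        demo_idx = demo.set_index("person_id")
        case_status = phenotypes.case_matrix(statuses)
        gia_series = gia.table.set_index("sample_id")["label"]
        gia_series = gia_series.reindex(case_status.index).dropna()
        sexspec = dict(
            zip(ontology["phecode"], ontology["sex_specific"])
        )
        scan = assoc.phecode_gia_scan(
            case_status,
            gia_series,
            demo_idx["age"],
            demo_idx["sex"],
            sex_specific=sexspec,
            alpha=config.alpha,
        )
        _write(scan.table, out / "gia_phecode_scan.tsv")
        thresholds = {
            "gia_phecode_bonferroni": scan.bonferroni_threshold,
            "alpha": config.alpha,
            "genome_wide_p": config.genome_wide_p,
        }
        (out / "assoc_thresholds.json").write_text(json.dumps(thresholds, indent=2))
        artifacts["gia_scan"] = "gia_phecode_scan.tsv"

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
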