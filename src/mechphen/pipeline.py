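"""End-to-end pipeline: QC -> association -> ranking -> enrichment.

All intermediates are files so stages can be re-run; no stage mutates its
inputs.  The resolved configuration is serialised next to the outputs for
provenance, and all randomness flows from the single configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import enrichment as enr
from . import forward as fwd
from . import io_formats as io
from . import qc as qc_mod
from . import reverse as rev

log = logging.getLogger("mechphen")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    genotypes: str  # PED/MAP prefix or dosage TSV path
    diagnoses: str
    icd9_groups: str
    group_phenotypes: str
    covariates: str
    out_dir: str
    genotype_format: str = "ped_map"
    annotation: str | None = None
    gene_map: str | None = None
    phenotypes: list[str] = field(default_factory=list)
    models: list[str] = field(default_factory=lambda: ["additive", "recessive", "rg1", "rg2"])
    qc: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    perm: rev.PermutationConfig = field(default_factory=rev.PermutationConfig)
    hwe_exclude: bool = False
    firth: bool = False
    enrichment_p_cut: float = 0.05
    enrichment_top_n: int | None = None
    enrichment_mode: str = "single_phenotype"
    seed: int = 0

    def validate(self) -> None:
        for name in ("genotypes", "diagnoses", "icd9_groups", "group_phenotypes", "covariates"):
            p = getattr(self, name)
            probe = Path(p + ".ped") if name == "genotypes" and self.genotype_format == "ped_map" else Path(p)
            if not probe.exists():
                raise ValueError(f"input file for {name!r} not found: {probe}")
        known = set(fwd.FORWARD_MODELS) | {"rg1", "rg2", "recessive_perm"}
        bad = set(self.models) - known
        if bad:
            raise ValueError(f"unknown model(s): {sorted(bad)}")


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Execute qc -> assoc/revgen -> rank -> enrich; returns output paths.

    Per-SNP failures are isolated: the SNP is flagged in the output with a
    reason and the run continues.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dump = asdict(cfg)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dump, fh, sort_keys=True)

    gm = io.read_genotypes(cfg.genotypes, cfg.genotype_format)
    if cfg.gene_map:
        gmap_df = pd.read_csv(cfg.gene_map, sep="\t", dtype=str)
        gm.gene_map = dict(zip(gmap_df["snp_id"], gmap_df["gene_id"]))
    cov = io.read_covariates(cfg.covariates)
    raw_dx = pd.read_csv(cfg.diagnoses, sep="\t", dtype=str)
    group_map = cohort_mod.load_group_map(cfg.icd9_groups, cfg.group_phenotypes)
    dx, n_unmapped = cohort_mod.map_to_groups(raw_dx, group_map)
    if n_unmapped:
        log.warning("%d diagnosis rows had unmapped ICD-9 codes", n_unmapped)

    roster = gm.subject_ids
    cov = cov.reindex(roster)
    if cov[["age", "gender", "dataset"]].isna().any().any():
        raise ValueError("covariates missing for some genotyped subjects")
    strata = rev.make_strata(cov, cfg.perm.age_bin).to_numpy()

    retained, report = qc_mod.select_snps(gm, cfg.qc, hwe_exclude=cfg.hwe_exclude)
    paths = {"qc_report": str(out / "qc_report.tsv")}
    io.write_results(report, paths["qc_report"])
    log.info("QC retained %d/%d SNPs", len(retained), gm.n_snps)

    phenotype_ids = cfg.phenotypes or sorted(
        {p for ps in group_map.group_to_phenotypes.values() for p in ps}
    )
    forward_rows, reverse_rows = [], []
    for pid in phenotype_ids:
        pdef = group_map.phenotype_def(pid)
        y = cohort_mod.assign_phenotype(dx, pdef, roster)
        groups = sorted(pdef.constituent_groups)
        D = rev.carrier_matrix(dx, roster, groups)
        for snp in retained:
            j = gm.snp_ids.index(snp)
            d = gm.dosages[:, j]
            gene = gm.gene_of(snp)
            for model in cfg.models:
                try:
                    if model in fwd.FORWARD_MODELS:
                        forward_rows.append(
                            fwd.fit_logistic(
                                d, y, cov, coding=model, snp_id=snp,
                                gene_id=gene, phenotype_id=pid, firth=cfg.firth,
                            )
                        )
                    else:
                        split = rev.split_homozygotes(d)
                        if split.n_hzma == 0:
                            reverse_rows.append(
                                {"snp_id": snp, "gene_id": gene, "phenotype_id": pid,
                                 "model": model, "tally": np.nan, "n_hzma": 0,
                                 "p": np.nan, "qualifying_groups": "",
                                 "flag": "no_hzma"}
                            )
                            continue
                        res = rev.stratified_permutation_p(
                            d, D, strata, model=model, cfg=cfg.perm,
                            groups=groups, snp_id=snp, snp_index=j,
                        )
                        reverse_rows.append(
                            {"snp_id": snp, "gene_id": gene, "phenotype_id": pid,
                             "model": model, "tally": res.tally,
                             "n_hzma": res.n_hzma, "p": res.p_perm,
                             "qualifying_groups": ",".join(res.qualifying_groups),
                             "flag": ""}
                        )
                except Exception as exc:  # isolate the failing SNP
                    log.warning("SNP %s %s/%s failed: %s", snp, pid, model, exc)
                    rowset = forward_rows if model in fwd.FORWARD_MODELS else reverse_rows
                    rowset.append(
                        {"snp_id": snp, "gene_id": gene, "phenotype_id": pid,
                         "model": model, "p": np.nan, "flag": f"error:{exc}"}
                    )
    if forward_rows:
        fdf = pd.DataFrame(forward_rows)
        paths["assoc"] = str(out / "assoc_forward.tsv")
        io.write_results(fdf, paths["assoc"])
    if reverse_rows:
        rdf = pd.DataFrame(reverse_rows)
        paths["revgen"] = str(out / "assoc_reverse.tsv")
        io.write_results(rdf, paths["revgen"])

    if cfg.annotation:
        ann = io.read_annotation(cfg.annotation)
        all_rows = (forward_rows or []) + (reverse_rows or [])
        df = pd.DataFrame(all_rows)
        for model in cfg.models:
            sub = df[df["model"] == model].copy()
            if model in fwd.FORWARD_MODELS:
                sub = fwd.or_filter(sub)
            sub = sub.dropna(subset=["p"])
            if sub.empty:
                log.warning("no usable results for enrichment, model=%s", model)
                continue
            mode = cfg.enrichment_mode
            if mode == "single_phenotype" and sub["phenotype_id"].nunique() > 1:
                mode = "pooled"
            ranked = enr.rank_genes(sub, mode=mode)
            scan = enr.sequential_scan(
                ranked, ann, p_cut=cfg.enrichment_p_cut, top_n=cfg.enrichment_top_n
            )
            key = f"enrichment_{model}"
            paths[key] = str(out / f"enrichment_{model}.tsv")
            io.write_results(scan, paths[key])
    return paths
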