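"""End-to-end orchestration: QC -> stratify -> per-stratum SNP tests + LD
-> gene-based combination -> codependence test -> report tables.

Each stage is a pure function of its inputs and the configured seed, so a
rerun with the same config and inputs is byte-identical.  Per-stratum
analyses are fully independent; significance is judged against the fixed
genome-wide thresholds (5e-8 per SNP, 2.5e-6 per gene) rather than an FDR.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import TRAITS, DataError, GenotypeMatrix
from .genes import GENE_GENOME_WIDE, SNP_GENOME_WIDE, genome_scan
from .io import read_gene_table, read_phenotypes, read_plink_text
from .ld import GeneModel, extend_by_ld, ld_pair_list, map_snps_to_gene
from .qc import default_qc, orient_minor_allele, stratify
from .assoc import allele_table, allelic_test, logistic_assoc
from .tau import tau_test, tau_test_adjusted


@dataclass
class PipelineConfig:
    plink_prefix: str = ""
    pheno_path: str = ""
    gene_path: str = ""
    out_dir: str = "results"
    min_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_threshold: float = 0.0001
    ld_list_threshold: float = 0.2
    ld_extend_threshold: float = 0.9
    upstream_kb: float = 20.0
    downstream_kb: float = 10.0
    snp_threshold: float = SNP_GENOME_WIDE
    gene_threshold: float = GENE_GENOME_WIDE
    traits: tuple = TRAITS
    covariates: tuple = ("age",)
    logistic_top_p: float = 1e-3  # run logistic only where allelic P <= this
    tau_adjusted_top_p: float = 1e-3
    tau_n_perm: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_threshold",
                     "snp_threshold", "gene_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise DataError(f"{name} must be in (0,1), got {v}")
        for name in ("ld_list_threshold", "ld_extend_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DataError(f"{name} must be in [0,1], got {v}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    qc: pd.DataFrame
    snp_results: pd.DataFrame
    ld_pairs: pd.DataFrame
    gene_results: pd.DataFrame
    codependence: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _stratum_label(key: tuple[str, str]) -> str:
    return f"{key[0]}_{key[1]}"


def analyze_stratum(
    G: GenotypeMatrix,
    S: pd.DataFrame,
    genes: pd.DataFrame,
    cfg: PipelineConfig,
    stratum: str,
) -> dict:
    """All per-stratum stages: QC (SNP side), SNP tests, LD, genes, tau."""
    if G.n_samples == 0:
        empty = pd.DataFrame()
        return {"snp": empty, "ld": empty, "gene": empty, "tau": empty, "qc": None}
    G, qc_rep = default_qc(G, cfg.min_call_rate, cfg.min_maf, cfg.hwe_threshold)
    G = orient_minor_allele(G)

    snp_rows = []
    per_trait_p: dict[str, pd.DataFrame] = {}
    for trait in cfg.traits:
        y = S[trait].to_numpy(dtype=float)
        valid = ~np.isnan(y)
        recs = []
        for j in range(G.n_snps):
            g = G.dosage[valid, j]
            yy = y[valid]
            sid = G.snp_meta["snp_id"][j]
            try:
                t = allele_table(g, yy)
                res = allelic_test(t)
            except DataError:
                continue
            recs.append(
                dict(
                    snp=sid,
                    stratum=stratum,
                    trait=trait,
                    test="allelic",
                    n_case=res.n_case,
                    n_control=res.n_control,
                    maf_case=res.maf_case,
                    maf_control=res.maf_control,
                    maf_overall=res.maf_overall,
                    OR=res.odds_ratio,
                    stat=res.statistic,
                    P=res.p_value,
                    flags=";".join(res.flags),
                )
            )
            if res.p_value <= cfg.logistic_top_p:
                lres = logistic_assoc(g, yy)
                recs.append(
                    dict(
                        snp=sid,
                        stratum=stratum,
                        trait=trait,
                        test="logistic",
                        n_case=lres.n_case,
                        n_control=lres.n_control,
                        maf_case=lres.maf_case,
                        maf_control=lres.maf_control,
                        maf_overall=lres.maf_overall,
                        OR=lres.odds_ratio,
                        stat=lres.statistic,
                        P=lres.p_value,
                        flags=";".join(lres.flags),
                    )
                )
        df = pd.DataFrame(recs)
        per_trait_p[trait] = df[df["test"] == "allelic"][["snp", "P"]].rename(
            columns={"P": "p"}
        ) if len(df) else pd.DataFrame(columns=["snp", "p"])
        snp_rows.append(df)
    snp_df = pd.concat([d for d in snp_rows if len(d)], ignore_index=True) if snp_rows else pd.DataFrame()

    ld_df = ld_pair_list(G, cfg.ld_list_threshold)
    ld_df.insert(0, "stratum", stratum)

    gene_models = []
    for _, row in genes.iterrows():
        gm = GeneModel(row["gene_id"], str(row["chrom"]), row["strand"], int(row["start"]), int(row["end"]))
        gm = map_snps_to_gene(gm, G.snp_meta, cfg.upstream_kb, cfg.downstream_kb)
        gm = extend_by_ld(gm, G, cfg.ld_extend_threshold)
        gene_models.append(gm)

    gene_rows = []
    for trait in cfg.traits:
        ptab = per_trait_p[trait].rename(columns={"snp": "snp_id"})
        if not len(ptab):
            continue
        gres = genome_scan(ptab, gene_models, G)
        gres.insert(0, "stratum", stratum)
        gres.insert(2, "trait", trait)
        gene_rows.append(gres)
    gene_df = pd.concat(gene_rows, ignore_index=True) if gene_rows else pd.DataFrame()

    # codependence: all six traits jointly vs each SNP (complete cases)
    Y = S[list(cfg.traits)].to_numpy(dtype=float)
    tau_rows = []
    rng_seed = int(
        hashlib.sha256(f"{cfg.seed}:{stratum}".encode()).hexdigest()[:8], 16
    ) % (2**31)
    for j in range(G.n_snps):
        g = G.dosage[:, j]
        keep = ~(np.isnan(g) | np.isnan(Y).any(axis=1))
        if keep.sum() < 2 or np.ptp(g[keep]) == 0:
            continue
        res = tau_test(Y[keep], g[keep], mode="analytic")
        p_adj = np.nan
        if res.p_value <= cfg.tau_adjusted_top_p and cfg.covariates:
            Z = S.loc[keep, list(cfg.covariates)].to_numpy(dtype=float)
            adj = tau_test_adjusted(
                Y[keep], g[keep], Z, n_perm=cfg.tau_n_perm, seed=rng_seed + j
            )
            p_adj = adj.p_value
        tau_rows.append(
            dict(
                stratum=stratum,
                snp=G.snp_meta["snp_id"][j],
                position=int(G.snp_meta["pos"][j]),
                P_unadjusted=res.p_value,
                P_adjusted=p_adj,
                df=res.df,
            )
        )
    tau_df = pd.DataFrame(tau_rows)
    return {"snp": snp_df, "ld": ld_df, "gene": gene_df, "tau": tau_df, "qc": qc_rep}


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full flow and write the report tables under ``out_dir``."""
    cfg.validate()
    try:
        G = read_plink_text(cfg.plink_prefix)
        S = read_phenotypes(cfg.pheno_path)
        genes = read_gene_table(cfg.gene_path)
    except Exception as exc:  # pragma: no cover - message shaping
        raise DataError(f"stage 'read inputs' failed: {exc}") from exc

    from .qc import sample_call_rate_filter

    G, callrate_rep = sample_call_rate_filter(G, cfg.min_call_rate)
    S = S[S["sample_id"].isin(set(G.sample_ids))].reset_index(drop=True)
    strata = stratify(G, S)

    qc_frames, snp_frames, ld_frames, gene_frames, tau_frames = [], [], [], [], []
    stratum_sizes = {}
    for key, (Gs, Ss) in strata.items():
        label = _stratum_label(key)
        stratum_sizes[label] = Gs.n_samples
        out = analyze_stratum(Gs, Ss, genes, cfg, label)
        if out["qc"] is not None:
            f = out["qc"].to_frame()
            f.insert(0, "stratum", label)
            qc_frames.append(f)
        for name, frames in (
            ("snp", snp_frames),
            ("ld", ld_frames),
            ("gene", gene_frames),
            ("tau", tau_frames),
        ):
            if len(out[name]):
                frames.append(out[name])

    def _cat(frames, columns):
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=columns)
        )

    report = RunReport(
        qc=_cat(qc_frames, ["stratum", "quantity", "count"]),
        snp_results=_cat(
            snp_frames,
            ["snp", "stratum", "trait", "test", "n_case", "n_control",
             "maf_case", "maf_control", "maf_overall", "OR", "stat", "P", "flags"],
        ),
        ld_pairs=_cat(ld_frames, ["stratum", "snp_i", "snp_j", "r2"]),
        gene_results=_cat(
            gene_frames,
            ["stratum", "gene_id", "trait", "m", "m_e", "p_gene", "argmin_j", "significant"],
        ),
        codependence=_cat(
            tau_frames,
            ["stratum", "snp", "position", "P_unadjusted", "P_adjusted", "df"],
        ),
        provenance={
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "version": __version__,
            "samples_removed_callrate": callrate_rep.n_samples_removed_callrate,
            "stratum_sizes": stratum_sizes,
        },
    )
    make_report_tables(report, cfg.out_dir)
    return report


def make_report_tables(report: RunReport, out_dir) -> list[Path]:
    """Write the TSV report tables (one per stage) plus provenance JSON."""
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, df in (
        ("qc_report", report.qc),
        ("snp_assoc", report.snp_results),
        ("ld_pairs", report.ld_pairs),
        ("gene_results", report.gene_results),
        ("codependence", report.codependence),
    ):
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    prov = out_dir / "provenance.json"
    with open(prov, "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
    written.append(prov)
    return written
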