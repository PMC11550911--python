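"""End-to-end orchestration: simulate/load inputs, run every stage in study
order, and write result tables plus a machine-readable summary and manifest.

Configuration is a flat set of stage-prefixed keys (strict: unknown keys are
rejected).  Every stochastic stage derives its own seed deterministically
from the master seed and the stage name, so stages can be rerun
independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, morpho, mtdna, outliers, popgen, pstfst, simulate

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of '<master>:<stage>', mod 2^31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters (flat, stage-prefixed)."""

    out_dir: str = "morphopop_run"
    seed: int = 0

    # inputs; empty string means "simulate this stream"
    tps_path: str = ""
    sliders_path: str = ""
    genotype_path: str = ""
    popmap_path: str = ""
    fasta_path: str = ""
    mtdna_enabled: bool = True

    # synthetic-data conditions (used when the matching input path is empty)
    sim_n_pops: int = 12
    sim_n_per_pop: int = 15
    sim_n_loci: int = 2000
    sim_fst: float = 0.118
    sim_sigma2_B: float = 2.0
    sim_sigma2_W: float = 1.0
    sim_n_seqs: int = 60
    sim_length_bp: int = 612
    sim_n_segsites: int = 42

    # filtering / outlier / popgen / pst parameters
    filter_locus_call_min: float = 0.95
    filter_ind_call_min: float = 0.85
    filter_maf_min: float = 0.05
    filter_one_per_tag: bool = True
    outlier_trim: float = 0.05
    outlier_he_min: float = 0.1
    outlier_q_thresh: float = 0.05
    outlier_k: int = 0               # 0 = automatic: n_populations - 1
    outlier_min_methods: int = 2
    fst_n_boot: int = 1000
    mantel_n_perm: int = 999
    dapc_k_max: int = 10
    dapc_n_pcs: int = 40
    pst_n_boot: int = 1000
    pst_n_traits: int = 3

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat key=value config; unknown keys are an error."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value, got {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"line {lineno}: unknown config key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON).

    Stage order: inputs (simulated where not supplied) → morphometrics →
    SNP filtering → outlier scan → neutral set → diversity / F_ST / Mantel /
    DAPC → P_ST traces and comparisons → mtDNA summaries.  A failure in one
    stage halts the run, preserving prior outputs and a status file.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}
    status = {"state": "running", "stage": None}

    def fail(stage: str, err: Exception) -> None:
        status.update(state="failed", stage=stage, error=str(err))
        (out / "status.json").write_text(json.dumps(status, indent=2))

    try:
        # ------------------------------------------------------------ inputs
        status["stage"] = "inputs"
        if cfg.genotype_path:
            g = io.read_genotypes(cfg.genotype_path)
            pm = io.read_popmap(cfg.popmap_path)
        else:
            g, pm, truth_g = simulate.simulate_genotypes(
                cfg.sim_n_pops, cfg.sim_n_per_pop, cfg.sim_n_loci, cfg.sim_fst,
                seed=stage_seed(cfg.seed, "genotypes"))
            io.write_genotype_csv(out / "genotypes.csv", g)
            io.write_popmap(out / "popmap.tsv", pm)
            io.write_truth(out / "genotypes.truth.txt", truth_g)
        if cfg.tps_path:
            configs = io.read_tps(cfg.tps_path, cfg.sliders_path or None)
        else:
            configs, truth_l = simulate.simulate_landmarks(
                cfg.sim_n_pops, cfg.sim_n_per_pop, cfg.sim_sigma2_B,
                cfg.sim_sigma2_W, nuisance=True,
                seed=stage_seed(cfg.seed, "landmarks"))
            io.write_tps(out / "landmarks.tps", configs)
            io.write_sliders(out / "landmarks.sliders.txt", configs[0].roles)
            io.write_truth(out / "landmarks.truth.txt", truth_l)
        seqs = None
        if cfg.mtdna_enabled:
            if cfg.fasta_path:
                seqs = io.read_fasta(cfg.fasta_path)
            else:
                seqs, truth_h = simulate.simulate_haplotypes(
                    cfg.sim_n_seqs, cfg.sim_length_bp, cfg.sim_n_segsites,
                    seed=stage_seed(cfg.seed, "haplotypes"))
                io.write_fasta(out / "coi.fasta", seqs)
                io.write_truth(out / "coi.truth.txt", truth_h)

        # ------------------------------------------------------ morphometrics
        status["stage"] = "morphometrics"
        aligned = morpho.gpa_align(configs, slide=configs[0].roles is not None)
        rw = morpho.relative_warps(aligned)
        rw.scores.to_csv(out / "rw_scores.csv")
        pd.DataFrame({"pct_variance": rw.pct_variance}).to_csv(out / "rw_variance.csv")
        lm_pops = np.array([c.population or c.specimen_id.split("_")[0] for c in configs])
        summary["rw1_pct_variance"] = float(rw.pct_variance[0])
        m = min(3, rw.scores.shape[1])
        if len(set(lm_pops)) >= 2 and m >= 1:
            mv = morpho.mancova_shape(rw.scores.iloc[:, :m].to_numpy(),
                                      aligned.centroid_size, lm_pops)
            summary["shape_mancova_F"] = mv["F"]
            summary["shape_mancova_p"] = mv["p"]

        # ------------------------------------------------------ SNP filtering
        status["stage"] = "filter"
        g_f, rep = popgen.filter_snps(
            g, cfg.filter_locus_call_min, cfg.filter_ind_call_min,
            cfg.filter_maf_min, cfg.filter_one_per_tag)
        (out / "filter_report.json").write_text(json.dumps(rep.counts, indent=2))
        summary["n_loci_postfilter"] = g_f.n_loci
        summary["n_individuals_postfilter"] = g_f.n_individuals

        # ------------------------------------------------------- outlier scan
        status["stage"] = "outliers"
        rep1 = outliers.trimmed_chisq_outliers(
            g_f, pm, cfg.outlier_trim, cfg.outlier_he_min, cfg.outlier_q_thresh)
        K = cfg.outlier_k or max(len(set(pm.labels_for(g_f.individuals))) - 1, 1)
        rep2 = outliers.pca_mahalanobis_outliers(g_f, K, cfg.outlier_q_thresh)
        cons = outliers.consensus([rep1, rep2], cfg.outlier_min_methods)
        pd.concat({m: t for m, t in cons.per_method.items()}, axis=1).to_csv(
            out / "outlier_scan.csv")
        (out / "neutral_loci.txt").write_text("\n".join(cons.neutral_set) + "\n")
        keep = [l in set(cons.neutral_set) for l in g_f.loci]
        g_n = g_f.subset_loci(np.array(keep))
        summary["n_neutral_loci"] = g_n.n_loci
        summary["n_consensus_outliers"] = len(cons.consensus_flagged)

        # --------------------------------------------- diversity / F_ST / DAPC
        status["stage"] = "popgen"
        div = popgen.diversity(g_n, pm)
        div.to_csv(out / "diversity.csv")
        res = popgen.wc_fst(g_n, pm)
        ci = popgen.bootstrap_fst_ci(res, n_boot=cfg.fst_n_boot,
                                     seed=stage_seed(cfg.seed, "fst_boot"))
        fst_mat = popgen.pairwise_fst(g_n, pm)
        fst_mat.to_csv(out / "pairwise_fst.csv")
        summary["global_fst"] = res.theta
        summary["global_fst_ci"] = list(ci)
        he_tab = popgen.per_locus_he(g_n, pm)
        contrast = popgen.diversity_contrast(he_tab)
        contrast["pairwise"].to_csv(out / "he_contrast.csv", index=False)
        summary["he_kruskal_p"] = contrast["kw_p"]
        dapc = popgen.dapc_cluster(g_n, cfg.dapc_k_max, cfg.dapc_n_pcs,
                                   seed=stage_seed(cfg.seed, "dapc"))
        dapc.bic.to_csv(out / "dapc_bic.csv")
        dapc.assignments.to_csv(out / "dapc_clusters.csv")
        summary["dapc_best_k"] = dapc.best_k
        if pm.coords_of:
            geo = popgen.geographic_distance_matrix(pm, log=True)
            r_ibd, p_ibd = popgen.mantel(
                geo.loc[fst_mat.index, fst_mat.index].to_numpy(),
                fst_mat.to_numpy(), n_perm=cfg.mantel_n_perm,
                seed=stage_seed(cfg.seed, "ibd"))
            summary["ibd_mantel_r"], summary["ibd_mantel_p"] = r_ibd, p_ibd

        # -------------------------------------------------------------- P_ST
        status["stage"] = "pst"
        order = {sid: i for i, sid in enumerate(aligned.specimen_ids)}
        cs = aligned.centroid_size
        traces = []
        pairwise_tables = {}
        for t in range(min(cfg.pst_n_traits, rw.scores.shape[1])):
            name = rw.scores.columns[t]
            trait = morpho_trait = rw.scores[name].to_numpy()
            adj = pstfst.size_adjust(morpho_trait, cs)
            trace = pstfst.trace_pst(
                adj, lm_pops, fst_global=res.theta, n_boot=cfg.pst_n_boot,
                seed=stage_seed(cfg.seed, f"pst_{name}"), trait_name=name)
            trace.to_frame().to_csv(out / f"pst_trace_{name}.csv", index=False)
            traces.append(trace)
            pairwise_tables[name] = pstfst.pairwise_pst(adj, lm_pops)
            pairwise_tables[name].to_csv(out / f"pairwise_pst_{name}.csv")
        summary["pst_phi1"] = {tr.trait: float(tr.pst_curve[np.argmin(np.abs(tr.phi_grid - 1.0))])
                               for tr in traces}
        summary["pst_robust"] = {tr.trait: tr.robust_flag for tr in traces}
        comp_rows = []
        shared = [p for p in fst_mat.index if p in pairwise_tables[traces[0].trait].index]
        for tr in traces:
            pmat = pairwise_tables[tr.trait].loc[shared, shared]
            fmat = fst_mat.loc[shared, shared]
            if pmat.isna().any().any():
                continue
            r, p = pstfst.compare_pst_fst(pmat, fmat, n_perm=cfg.mantel_n_perm,
                                          seed=stage_seed(cfg.seed, f"cmp_{tr.trait}"))
            comp_rows.append({"trait": tr.trait, "mantel_r": r, "p": p})
        pd.DataFrame(comp_rows).to_csv(out / "pst_fst_comparison.csv", index=False)

        # -------------------------------------------------------------- mtDNA
        if cfg.mtdna_enabled and seqs is not None:
            status["stage"] = "mtdna"
            haps = mtdna.collapse_haplotypes(seqs)
            dist = mtdna.pdistance_matrix(seqs)
            dist.to_csv(out / "coi_pdistance.csv")
            newick = mtdna.nj_tree(haps.distance_matrix)
            (out / "coi_nj.nwk").write_text(newick + "\n")
            net = mtdna.mst_network(haps)
            pd.DataFrame(net["edges"], columns=["hap1", "hap2", "steps"]).to_csv(
                out / "coi_network.csv", index=False)
            iu = np.triu_indices(len(dist), k=1)
            summary["n_haplotypes"] = haps.n_haplotypes
            summary["n_segregating_sites"] = mtdna.segregating_sites(seqs)
            summary["max_p_distance_pct"] = float(np.nanmax(dist.to_numpy()[iu]))
            summary["mean_p_distance_pct"] = float(np.nanmean(dist.to_numpy()[iu]))

        status.update(state="done", stage=None)
    except Exception as err:      # noqa: BLE001 - halt with partial outputs
        fail(status["stage"], err)
        raise

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    manifest = {
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in
                        ("genotypes", "landmarks", "haplotypes", "fst_boot",
                         "dapc", "ibd")},
        "config": {f.name: getattr(cfg, f.name) for f in fields(cfg)},
        "outputs": {p.name: _sha256(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "status.json").write_text(json.dumps(status, indent=2))
    return summary
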