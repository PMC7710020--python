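"""End-to-end pipeline: simulate -> call -> classify -> accessibility ->
motifs -> gene sets -> profiles, with deterministic TSV/BED outputs.

A scenario is described by a YAML config (or the built-in default);
every stage writes its outputs under the run directory and a JSON log
records the seed and parameters so a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth, events, accessibility, motifs, genesets, profiles
from .core import write_fasta, write_bed


def load_config(path=None) -> dict:
    """Read a scenario config; missing keys fall back to defaults."""
    cfg = {
        "n_sites_per_category": 800,
        "n_genes": 2000,
        "genes_per_category": 120,
        "n_null_motif_seqs": 20_000,
        "motif_fdr_target": 0.1,
        "write_tag_libraries": False,
    }
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def _fmt(df: pd.DataFrame, path: Path, params: dict | None = None) -> None:
    """Deterministic TSV writer with a parameter header comment."""
    with open(path, "w") as fh:
        if params:
            fh.write("# " + json.dumps(params, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(outdir, seed: int = 1, config: dict | None = None,
                 config_path=None) -> dict:
    """Run the full synthetic-scenario analysis; returns a result summary."""
    cfg = load_config(config_path)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed)

    # ---- simulate -------------------------------------------------------
    lcfg = synth.default_config(cfg["n_sites_per_category"])
    tf_specs = synth.default_tf_specs()
    genome0 = synth.generate_genome(lcfg, seed=rng_seed)
    genome, truth = synth.plant_landscape(genome0, lcfg, tf_specs,
                                          seed=rng_seed + 1)
    chip = {tf.name: synth.simulate_chip(truth, tf, seed=rng_seed + 10 + i)
            for i, tf in enumerate(tf_specs)}
    input_lib = synth.simulate_input(truth, seed=rng_seed + 20)[0]
    atac_prior = synth.simulate_atac(truth, mode="prior", seed=rng_seed + 30)
    # each TF induced separately, as in a per-TF induction design
    atac_post = {tf.name: synth.simulate_atac(truth, [tf], mode="post",
                                              seed=rng_seed + 31 + i)
                 for i, tf in enumerate(tf_specs)}
    genes, expr = synth.simulate_expression(truth, seed=rng_seed + 40,
                                            n_genes=cfg["n_genes"],
                                            genes_per_category=cfg["genes_per_category"])

    write_fasta(genome, out / "genome.fa")
    _fmt(truth.sites, out / "truth_sites.tsv", {"seed": rng_seed})
    write_bed(truth.domains, out / "truth_domains.bed",
              chrom_order=genome.chrom_names)
    _fmt(genes, out / "gene_models.tsv")
    _fmt(expr, out / "expression.tsv")
    if cfg["write_tag_libraries"]:
        from .core import write_tags
        for tf, libs in chip.items():
            for lib in libs:
                write_tags(lib, out / f"chip_{tf}_{lib.replicate_id}.bed",
                           chrom_order=genome.chrom_names)

    # ---- call + classify ------------------------------------------------
    tcfg = events.TestConfig()
    called = {tf: events.call_events(libs, input_lib, genome, tcfg)
              for tf, libs in chip.items()}
    top = {tf: events.rank_top(ev, tcfg.top_n) for tf, ev in called.items()}
    for tf, ev in top.items():
        _fmt(ev, out / f"events_{tf}.tsv", {"seed": rng_seed, "tf": tf})
    cat = events.classify_multiway(top, chip, input_lib, tcfg)
    _fmt(cat.sites, out / "categories.tsv",
         {"seed": rng_seed, "dispersion": cat.dispersion})

    truth_match = events.match_to_truth(cat.sites, truth.sites)
    matched = truth_match.notna() & (truth_match != "control")
    agree = (cat.sites["label"][matched] == truth_match[matched])
    recovery = float(agree.mean()) if matched.any() else float("nan")

    # ---- accessibility --------------------------------------------------
    domains = accessibility.call_domains(atac_prior, genome)
    write_bed(domains, out / "domains.bed", chrom_order=genome.chrom_names)
    dens_rows = []
    frac_rows = []
    labels = [lab for lab in cat.sites["label"].unique()
              if lab != events.UNCLASSIFIED]
    for lab in sorted(labels):
        sub = cat.sites[cat.sites["label"] == lab]
        dens, summary = accessibility.site_density(sub, atac_prior)
        dens_rows.append({"label": lab, "n": summary.n,
                          "median_tpm": summary.median,
                          "q1": summary.q1, "q3": summary.q3})
        frac_rows.append({"label": lab,
                          "fraction_in_domains":
                          accessibility.fraction_in_domains(sub, domains)})
    _fmt(pd.DataFrame(dens_rows), out / "prior_density.tsv")
    _fmt(pd.DataFrame(frac_rows), out / "domain_overlap.tsv")
    sites_cat = cat.sites.rename(columns={"label": "category"})
    change_frames = []
    for tf_name, post_libs in atac_post.items():
        _delta, delta_summary = accessibility.accessibility_change(
            sites_cat, atac_prior, post_libs)
        delta_summary.insert(0, "induced_tf", tf_name)
        change_frames.append(delta_summary)
    _fmt(pd.concat(change_frames, ignore_index=True),
         out / "accessibility_change.tsv")
    comp = accessibility.composite_profile(cat.sites, atac_prior)
    _fmt(pd.DataFrame({"offset": np.arange(-1000, 1000), "density": comp}),
         out / "composite_shared.tsv")

    # ---- motifs ---------------------------------------------------------
    bg = motifs.train_background(genome)
    null_seqs = motifs.sample_codes(bg, cfg["n_null_motif_seqs"], 100,
                                    seed=rng_seed + 50)
    motif_models = synth.default_motifs()
    motif_rows = []
    for mname in ("anterior", "posterior", "bipartite"):
        sm = motifs.ScoredMotif.from_motif(motif_models[mname], bg)
        query = motifs.embed_motif_instances(
            motif_models[mname], bg, 2_000, seed=rng_seed + 51)
        try:
            motifs.calibrate_threshold(sm, query, null_seqs,
                                       cfg["motif_fdr_target"])
        except motifs.NoDiscriminativeThreshold:
            continue
        for lab in sorted(labels):
            sub = cat.sites[cat.sites["label"] == lab]
            flags, _hits = motifs.peaks_with_hits(sub, genome, sm)
            over = motifs.overrepresentation(int(flags.sum()), len(flags),
                                             genome, sm, seed=rng_seed + 52)
            motif_rows.append({"motif": mname, "label": lab,
                               "hit_rate": float(flags.mean()),
                               "rate_ratio": over["rate_ratio"],
                               "p": over["p"],
                               "threshold": sm.threshold})
    _fmt(pd.DataFrame(motif_rows), out / "motif_enrichment.tsv")

    # ---- gene sets ------------------------------------------------------
    gene_sets = genesets.build_gene_sets(expr, tf_names=[t.name for t in tf_specs])
    cat_peaks = {lab: cat.sites[cat.sites["label"] == lab][["chrom", "point"]]
                 for lab in sorted(labels)}
    assoc = genesets.association_matrix(cat_peaks, gene_sets, genes)
    _fmt(assoc, out / "associations.tsv")

    # ---- profiles -------------------------------------------------------
    union = profiles.union_top_sites(top)
    libs_flat = {f"{tf}_{lib.replicate_id}": lib
                 for tf, libs in chip.items() for lib in libs}
    cmat = profiles.profile_count_matrix(union, libs_flat)
    pca = profiles.pca_profiles(cmat)
    _fmt(pca.scores.reset_index(names="experiment"), out / "pca_scores.tsv")
    _fmt(pd.DataFrame({"component": [f"PC{i+1}" for i in
                                     range(len(pca.variance_fraction))],
                       "variance_fraction": pca.variance_fraction}),
         out / "pca_variance.tsv")
    hm = profiles.heatmap_matrix(top[tf_specs[0].name], chip[tf_specs[0].name][0],
                                 genome)
    _fmt(pd.DataFrame(hm.matrix), out / "heatmap_A_rep1.tsv",
         {"vmin": hm.vmin, "vmax": hm.vmax})

    log = {"seed": rng_seed, "config": cfg,
           "n_sites": int(len(truth.sites)),
           "n_classified": int(len(cat.sites)),
           "category_recovery": recovery,
           "dispersion": cat.dispersion}
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
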