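"""End-to-end pipeline driver tying all stages into a reproducible run.

Stages: synthetic genome -> MA simulation -> call-record emission ->
callable mask -> filter cascade -> rate/overdispersion/clustering
statistics -> spectrum -> context features -> mutability model. Every
random stage derives its seed from the master seed; every output table
carries the config hash and seed in a header comment, and stages are
independently invocable through the library (or `mamut` subcommands).
"""
from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, io, mutability, rates, seqcontext, spectrum, synth

#: default run configuration: 2 Mb genome, 26 lines, 788 generations.
#: base_mu is scaled up by the genome-shrink factor (129.2 Mb -> 2 Mb) so
#: the expected mutation yield (~2,600 events over 26 lines) matches the
#: full-scale experiment this emulates.
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "genome": {"n_contigs": 4,
               "lengths": [800_000, 600_000, 400_000, 200_000],
               "gc": 0.66, "repeat_density": 0.2},
    "experiment": {"n_lines": 26, "t": 788.0, "base_mu": 6.37e-8,
                   "line_meanlog": -3.01, "line_sdlog": 1.15,
                   "indel_fraction": 618 / 2609},
    "noise": {"realistic": True},
    "probes": {"spacing": 27_000},
    "thresholds": {},
    "clustering": {"iters": 1000,
                   "window_sizes": [1_000, 10_000, 100_000, 500_000]},
    "poisson_sim": {"reps": 1000},
    "context": {"lc_max_k": 16},
    "model": {"enabled": True, "replicates": 10, "n_nonmutated": 4000,
              "n_test_random": 20_000, "cv_folds": 10, "cs": 5},
    "exclude_lines": [],
}


def small_config(seed: int = 1) -> dict:
    """A reduced configuration for quick runs: 300 kb, lighter model."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cfg["seed"] = seed
    cfg["genome"].update(n_contigs=2, lengths=[200_000, 100_000])
    cfg["experiment"]["base_mu"] = 4.2e-7  # keeps ~100 events per line
    cfg["clustering"]["iters"] = 300
    cfg["poisson_sim"]["reps"] = 500
    cfg["model"].update(replicates=3, n_nonmutated=1500,
                        n_test_random=5000, cv_folds=5, cs=4)
    return cfg


def merge_config(overrides: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | None = None, out_dir=None,
                 seed: int | None = None) -> dict:
    """Run the full analysis on a synthetic experiment; return the report.

    With ``out_dir`` set, all stage outputs (FASTA/VCF/BED/TSV tables and
    report.json) are written there; rerunning with the same config and
    seed reproduces them byte-identically.
    """
    cfg = merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    chash = io.config_hash(cfg)
    master = np.random.default_rng(cfg["seed"])
    seeds = {name: int(s) for name, s in zip(
        ("genome", "sim", "emit", "clustering", "poisson", "model",
         "context"),
        master.integers(2 ** 31 - 1, size=7))}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        io.ensure_dir(out)

    gcfg = cfg["genome"]
    genome = synth.generate_genome(
        gcfg["n_contigs"], gcfg["lengths"], gcfg["gc"],
        gcfg["repeat_density"], seed=seeds["genome"])
    ecfg = cfg["experiment"]
    truth = synth.simulate_ma_experiment(
        genome, n_lines=ecfg["n_lines"], t=ecfg["t"],
        base_mu=ecfg["base_mu"],
        line_dist=(ecfg["line_meanlog"], ecfg["line_sdlog"]),
        indel_fraction=ecfg["indel_fraction"], seed=seeds["sim"])
    probes = synth.spike_in_probes(genome, cfg["probes"]["spacing"])
    noise = (synth.NoiseModel.realistic() if cfg["noise"].get("realistic")
             else synth.NoiseModel(**{k: v for k, v in cfg["noise"].items()
                                      if k != "realistic"}))
    cs = synth.emit_call_records(genome, truth, noise=noise,
                                 seed=seeds["emit"], probes=probes)

    thresholds = calling.CallingThresholds(**cfg["thresholds"])
    mask = calling.build_callable_mask(cs, thresholds)
    result = calling.call_candidate_mutations(cs, mask, thresholds)
    accepted = result.accepted
    # probe bookkeeping: emitted round-robin over sorted lines
    lines_sorted = sorted(truth.line_rates)
    probe_lines = {(p.contig, p.pos): lines_sorted[i % len(lines_sorted)]
                   for i, p in enumerate(probes)}
    probe_keys = set(probe_lines)
    muts = [m for m in accepted if (m.contig, m.pos) not in probe_keys]
    recovered_probes = [m for m in accepted
                        if (m.contig, m.pos) in probe_keys]
    callability = calling.spike_in_callability(probes, recovered_probes,
                                               probe_lines)
    contamination = calling.contamination_screen(cs)

    # rates ---------------------------------------------------------------
    excluded = list(cfg["exclude_lines"])
    n_lines_eff = ecfg["n_lines"] - len(excluded)
    t = ecfg["t"]
    nc = mask.total()
    snms = [m for m in muts if m.kind == "SNM"
            and m.line_id not in excluded]
    rate_rows = []
    for kind in ("SNM", "DEL", "INS"):
        n_mu = sum(1 for m in muts
                   if m.kind == kind and m.line_id not in excluded)
        est = rates.mutation_rate(n_mu, nc, n_lines_eff, t, stratum=kind)
        rate_rows.append({"stratum": kind, "n_mu": n_mu, "n_c": nc,
                          "n_lines": n_lines_eff, "t": t, "mu": est.mu})
    per_line = pd.Series({line: 0 for line in truth.line_rates})
    for m in muts:
        if m.kind == "SNM":
            per_line[m.line_id] += 1
    for line, count in per_line.items():
        est = rates.mutation_rate(count, nc, 1, t, stratum=f"line:{line}")
        rate_rows.append({"stratum": f"line:{line}", "n_mu": count,
                          "n_c": nc, "n_lines": 1, "t": t, "mu": est.mu})
    rates_df = pd.DataFrame(rate_rows)

    counts = per_line.drop(index=excluded, errors="ignore")
    fits = rates.fit_count_distributions(counts.to_numpy())
    fits_df = pd.DataFrame([{
        "distribution": f.name, "aic": f.aic, "loglik": f.loglik,
        "ks_d": f.ks_d, "ks_p": f.ks_p, "ok": f.ok,
        **{f"param_{k}": v for k, v in f.params.items()}} for f in fits])
    over = rates.overdispersion_test(counts, seed=seeds["poisson"])
    snm_rate = rates_df.loc[rates_df["stratum"] == "SNM", "mu"].iloc[0]
    psim = rates.simulate_poisson_ma(
        snm_rate, nc, n_lines_eff, t, reps=cfg["poisson_sim"]["reps"],
        seed=seeds["poisson"])
    ccfg = cfg["clustering"]
    imd = rates.imd_test(snms, mask, iters=ccfg["iters"],
                         seed=seeds["clustering"], genome=genome)
    windows = rates.window_clustering(
        snms, mask, sizes=tuple(ccfg["window_sizes"]),
        iters=ccfg["iters"], seed=seeds["clustering"] + 1)

    # spectrum ------------------------------------------------------------
    spec_counts = spectrum.spectrum_counts(
        m for m in muts if m.kind == "SNM")
    spec = spectrum.gc_corrected_spectrum(spec_counts, genome.gc()) \
        if sum(spec_counts.values()) else None

    # context + model -----------------------------------------------------
    report_model = {}
    model_tables = {}
    if cfg["model"].get("enabled", True) and snms:
        ctx_cfg = seqcontext.ContextConfig(
            lc_max_k=cfg["context"]["lc_max_k"])
        rng = np.random.default_rng(seeds["context"])
        mcfg = cfg["model"]
        mut_sites = pd.DataFrame(
            {"contig": [m.contig for m in snms],
             "pos": [m.pos for m in snms]})
        mut_keys = set(zip(mut_sites["contig"], mut_sites["pos"]))
        pool_n = mcfg["n_nonmutated"] + mcfg["n_test_random"]
        rand_sites = _random_callable_sites(rng, mask, pool_n, mut_keys)
        all_sites = pd.concat([mut_sites, rand_sites], ignore_index=True)
        feats = seqcontext.context_features(genome, all_sites,
                                            config=ctx_cfg)
        labels = np.r_[np.ones(len(mut_sites)), np.zeros(len(rand_sites))]
        train_rows = np.r_[np.arange(len(mut_sites)),
                           len(mut_sites) + np.arange(mcfg["n_nonmutated"])]
        matrix = mutability.build_feature_matrix(
            feats.iloc[train_rows].drop(columns=["contig"]),
            labels[train_rows])
        cs_grid = np.logspace(-3, 2, int(mcfg.get("cs", 5)))
        model = mutability.train_mutability(
            matrix, n_nonmutated=mcfg["n_nonmutated"],
            cv_folds=mcfg["cv_folds"], replicates=mcfg["replicates"],
            cs=cs_grid, seed=seeds["model"])
        test_rows = np.r_[np.arange(len(mut_sites)),
                          len(mut_sites) + mcfg["n_nonmutated"]
                          + np.arange(len(rand_sites)
                                      - mcfg["n_nonmutated"])]
        test_labels = labels[test_rows]
        test_frame = mutability.encode_features(
            feats.iloc[test_rows].drop(columns=["contig"])
            .reset_index(drop=True))
        calib = mutability.calibrate_predictions(
            model, test_frame, test_labels[test_frame.index.to_numpy()])
        coefs = model.coefficient_summary()
        model_tables = {"coefficients": coefs.reset_index(names="predictor"),
                        "calibration": calib.table,
                        "model": model.to_frame(),
                        "features": feats}
        report_model = {
            "calibration_slope": calib.slope, "calibration_r2": calib.r2,
            "top_predictors": coefs["median"].abs().sort_values(
                ascending=False).head(10).index.tolist()}

    report = {
        "config_hash": chash, "seed": cfg["seed"],
        "genome_length": genome.total_length, "genome_gc": genome.gc(),
        "callable_sites": int(nc),
        "callable_fraction": nc / genome.total_length,
        "n_accepted": len(muts),
        "n_snm": len([m for m in muts if m.kind == "SNM"]),
        "n_del": len([m for m in muts if m.kind == "DEL"]),
        "n_ins": len([m for m in muts if m.kind == "INS"]),
        "mu_snm": float(snm_rate),
        "overdispersion_ratio": over.ratio,
        "best_fit_distribution": next((f.name for f in fits if f.ok), None),
        "poisson_sim_median_variance": psim.median_variance,
        "imd_p": imd.ks_p,
        "window_p": {int(r.window_size): float(r.p)
                     for r in windows.per_size.itertuples(index=False)},
        "spectrum_deviation": (spec.deviation if spec else {}),
        "spike_in_callability": float(
            callability.loc[callability["line_id"] == "__all__",
                            "rate"].iloc[0]),
        "n_contamination_flags": int(contamination["flagged"].sum()),
        **report_model,
    }

    if out is not None:
        io.write_fasta(genome, out / "genome.fa")
        io.write_bed(genome.annotation, out / "annotation.bed",
                     name_col="feature")
        io.write_bed(genome.repeats, out / "repeats.bed",
                     name_col="repeat_class")
        io.write_vcf(cs, out / "calls.vcf")
        io.write_mask_bed(mask, out / "mask.bed")
        io.write_table(io.mutations_to_frame(truth.mutations),
                       out / "truth.tsv", chash, cfg["seed"])
        io.write_table(io.mutations_to_frame(muts), out / "mutations.tsv",
                       chash, cfg["seed"])
        io.write_table(rates_df, out / "rates.tsv", chash, cfg["seed"])
        io.write_table(fits_df, out / "fits.tsv", chash, cfg["seed"])
        io.write_table(callability, out / "spike_in_callability.tsv",
                       chash, cfg["seed"])
        io.write_table(contamination, out / "contamination.tsv",
                       chash, cfg["seed"])
        io.write_table(windows.per_size, out / "window_clustering.tsv",
                       chash, cfg["seed"])
        io.write_table(imd.short_range, out / "imd_short_range.tsv",
                       chash, cfg["seed"])
        if spec is not None:
            io.write_table(spec.to_frame(), out / "spectrum.tsv",
                           chash, cfg["seed"])
            spectrum.plot_deviation(spec, out / "spectrum.png")
        for name, df in model_tables.items():
            io.write_table(df, out / f"{name}.tsv", chash, cfg["seed"])
        io.save_config(cfg, out / "config.yaml")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


def _random_callable_sites(rng, mask, n: int, exclude: set
                           ) -> pd.DataFrame:
    """Sample callable sites uniformly without replacement, excluding
    mutated positions."""
    pools = {c: mask.positions(c) for c in mask.intervals}
    sizes = {c: len(p) for c, p in pools.items()}
    total = sum(sizes.values())
    if total == 0:
        raise ValueError("empty callable mask")
    n = min(n, total - len(exclude))
    contigs = list(pools)
    probs = np.array([sizes[c] for c in contigs], dtype=float) / total
    picks = rng.multinomial(n, probs)
    rows = []
    for c, k in zip(contigs, picks):
        chosen: set[int] = set()
        pool = pools[c]
        while len(chosen) < k:
            for p in pool[rng.integers(0, len(pool),
                                       size=k - len(chosen))]:
                key = (c, int(p))
                if key not in exclude and int(p) not in chosen:
                    chosen.add(int(p))
                if len(chosen) >= k:
                    break
        rows.extend((c, p) for p in sorted(chosen))
    return pd.DataFrame(rows, columns=["contig", "pos"])
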