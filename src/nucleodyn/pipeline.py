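"""End-to-end orchestration: config, staged run, manifest, summary report.

A run is driven by a flat YAML config (unknown keys are rejected).  All
randomness flows from the single global seed through per-stage spawned
generators; the resolved config and a manifest with SHA-256 checksums of
every output are written beside the results, so a rerun with the same seed
is verifiably identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as ct
from . import domains as dm
from . import genome_io as gio
from . import metagene as mg
from . import nucleosomes as nc
from . import occupancy as oc
from . import simulate as sim

log = logging.getLogger("nucleodyn")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "enabled": True,
        "genome_length": 8_000_000,
        "nrl": 190,
        "frag_len_mean": 147.0,
        "frag_len_sd": 10.0,
        "occupancy": 20.0,
        "n_genes": 60,
        "gene_length": 10_000,
        "n_peaks": 150,
        "tf_enrichment_odds": 4.0,
        "n_depletions": 12,
        "depletion_size": 25_000,
        "depletion_factor": 0.5,
        "n_shift_arrays": 20,
        "shift_bp": 15,
        "contact_background_rate": 0.05,
        "contact_signal_rate": 0.9,
    },
    "inputs": {
        "fragments_t1": None,
        "fragments_t2": None,
        "chrom_sizes": None,
        "genes_bed12": None,
        "gene_counts": None,
        "tf_peaks": None,
        "inert_bed": None,
        "contact_table": None,
        "contact_viewpoint": None,
    },
    "occupancy": {
        "window": 5_000,
        "pseudocount": 0.5,
        "min_count": 20,
        "alpha": 0.05,
        "correction": "bh",
        "min_inert": 100,
        "smooth_span": 5,
    },
    # raw-p labelling at coarse scales: an empirical null of a few hundred
    # windows floors p at 1/(m+1), which BH can never reject for a handful
    # of discoveries
    "domains": {"scales": [5_000, 25_000, 50_000, 100_000], "correction": "none"},
    # min_height_rel is relative to the mean per-bp midpoint density; positioned
    # dyad peaks stand ~2x above homogeneous chromatin at demo coverage
    "reposition": {"bandwidth": 30.0, "min_separation": 147, "shift_threshold": 10,
                   "min_height_rel": 1.2},
    "metagene": {"body_bins": 100, "flank": 5_000, "flank_bin": 50},
    "embed": {"min_frac": 0.25, "promoter_flank": 1_000},
    "contacts": {"wmin": 2_000, "wmax": 200_000, "n_sizes": 12, "n_perm": 200,
                 "fdr": 0.01, "n_background": 3_000},
}


def _check_keys(config: dict, defaults: dict, path: str = "") -> None:
    for key, value in config.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            _check_keys(value, defaults[key], path + key + ".")


def resolve_config(overrides: dict | None = None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    if overrides:
        _check_keys(overrides, DEFAULT_CONFIG)
        for key, value in overrides.items():
            if isinstance(value, dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def load_config(path: str | os.PathLike | None) -> dict:
    if path is None:
        return resolve_config()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return resolve_config(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_inputs(config: dict, outdir: Path, rng_parent: np.random.SeedSequence) -> dict:
    p = config["simulate"]
    seeds = rng_parent.spawn(6)
    spec = sim.LandscapeSpec(
        genome_length=p["genome_length"],
        nrl=p["nrl"],
        frag_len_mean=p["frag_len_mean"],
        frag_len_sd=p["frag_len_sd"],
        base_occupancy=p["occupancy"],
        seed=config["seed"],
    )
    index = spec.index
    chrom = index.names[0]
    chrom_len = index.length(chrom)
    rng_events = np.random.default_rng(seeds[0])
    starts = sim._place_nonoverlapping(
        rng_events, p["n_depletions"], p["depletion_size"], chrom_len, gap=p["depletion_size"]
    )
    events = [
        sim.PlantedEvent("depletion", chrom, int(s), int(s) + p["depletion_size"],
                         factor=p["depletion_factor"])
        for s in starts
    ]
    truth, genes, counts, peaks = sim.simulate_annotations(
        spec,
        n_genes=p["n_genes"],
        gene_length=p["gene_length"],
        tf_enrichment_odds=p["tf_enrichment_odds"],
        n_peaks=p["n_peaks"],
        seed=np.random.default_rng(seeds[1]),
        events=events,
    )
    expressed = truth.gene_classes[truth.gene_classes["gene_class"] != "unexpressed"]
    track0 = sim.simulate_landscape(
        spec, genes[genes["name"].isin(expressed["gene"])]
    )
    # plant dyad shifts on phased arrays (expressed gene bodies) clear of the
    # depletion events
    dep_iv = [(e.start, e.end) for e in events]
    n_shifts = 0
    for _, g in expressed.iterrows():
        if n_shifts >= p["n_shift_arrays"]:
            break
        if any(g["start"] < e and g["end"] > s for s, e in dep_iv):
            continue
        events.append(
            sim.PlantedEvent("shift", chrom, int(g["start"]), int(g["end"]),
                             shift_bp=p["shift_bp"])
        )
        n_shifts += 1
    truth.events = list(events)
    track_t2 = sim.apply_events(track0, events)
    frags1 = sim.sample_fragments(track0, p["occupancy"], p["frag_len_mean"],
                                  p["frag_len_sd"], seed=np.random.default_rng(seeds[2]))
    frags2 = sim.sample_fragments(track_t2, p["occupancy"], p["frag_len_mean"],
                                  p["frag_len_sd"], seed=np.random.default_rng(seeds[3]))

    ends = sim.simulate_fragment_ends(chrom_len, seed=np.random.default_rng(seeds[4]))
    targets = truth.events_frame()
    targets = targets[targets["kind"] == "depletion"].head(3)[["chrom", "start", "end"]]
    contact_table = sim.simulate_contacts(
        int(ends[len(ends) // 2]),
        ends,
        targets,
        signal_rate=p["contact_signal_rate"],
        background_rate=p["contact_background_rate"],
        seed=np.random.default_rng(seeds[5]),
    )
    truth.contact_targets = targets

    simdir = outdir / "simulated"
    simdir.mkdir(parents=True, exist_ok=True)
    gio.write_chrom_sizes(index, simdir / "genome.chrom.sizes")
    gio.write_bed12(genes, simdir / "genes.bed12")
    gio.write_table(counts, simdir / "gene_counts.tsv")
    gio.write_narrowpeak(peaks, simdir / "tf_peaks.narrowPeak")
    gio.write_table(truth.inert_regions, simdir / "inert_regions.tsv")
    gio.write_table(truth.events_frame(), simdir / "truth_events.tsv")
    gio.write_table(truth.gene_classes, simdir / "truth_gene_classes.tsv")
    gio.write_table(contact_table, simdir / "contacts.tsv")
    for label, frags in (("t1", frags1), ("t2", frags2)):
        bed = pd.concat(
            [df.assign(chrom=c)[["chrom", "start", "end"]] for c, df in frags.items()]
        )
        gio.write_bed(bed, simdir / f"fragments_{label}.bed")
    return {
        "index": index,
        "genes": genes,
        "counts": counts,
        "peaks": peaks,
        "inert": truth.inert_regions,
        "truth": truth,
        "mid1": sim.fragments_to_midpoints(frags1),
        "mid2": sim.fragments_to_midpoints(frags2),
        "contact_table": contact_table,
        "viewpoint": int(ends[len(ends) // 2]),
        "contact_chrom": chrom,
    }


def _load_inputs(config: dict) -> dict:
    paths = config["inputs"]
    required = ("fragments_t1", "fragments_t2", "chrom_sizes", "genes_bed12", "gene_counts")
    missing = [k for k in required if not paths[k]]
    if missing:
        raise ValueError(f"simulate disabled but inputs missing: {', '.join(missing)}")
    index = gio.read_chrom_sizes(paths["chrom_sizes"])
    genes = gio.read_genes(paths["genes_bed12"], index=index)
    counts = gio.read_table(paths["gene_counts"])
    data = {
        "index": index,
        "genes": genes,
        "counts": counts,
        "mid1": gio.read_fragments(paths["fragments_t1"], index=index),
        "mid2": gio.read_fragments(paths["fragments_t2"], index=index),
        "peaks": gio.read_intervals(paths["tf_peaks"], "narrowPeak", index=index)
        if paths["tf_peaks"]
        else None,
        "inert": gio.read_intervals(paths["inert_bed"], "BED", index=index)
        if paths["inert_bed"]
        else None,
        "truth": None,
    }
    if paths["contact_table"]:
        data["contact_table"] = gio.read_table(paths["contact_table"])
        chrom, pos = str(paths["contact_viewpoint"]).split(":")
        data["viewpoint"] = int(pos)
        data["contact_chrom"] = chrom
    else:
        data["contact_table"] = None
    return data


def run_all(config: dict, outdir: str | os.PathLike) -> dict:
    """Run every stage in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_parent = np.random.SeedSequence(config["seed"])
    stage_seeds = dict(zip(("simulate", "contacts"), seed_parent.spawn(2)))

    if config["simulate"]["enabled"]:
        log.info("stage simulate")
        data = _simulate_inputs(config, outdir, stage_seeds["simulate"])
    else:
        data = _load_inputs(config)

    ocfg = config["occupancy"]
    log.info("stage occupancy (window %d)", ocfg["window"])
    grid = oc.tile_genome(data["index"], ocfg["window"])
    classes = mg.classify_genes(
        data["counts"]["count_t1"], data["counts"]["count_t2"], data["counts"]["gene"]
    )
    expressed_names = classes.table.loc[
        classes.table["gene_class"].isin(("up", "down", "constitutive")), "gene"
    ]
    expressed_genes = data["genes"][data["genes"]["name"].isin(expressed_names)]
    if data.get("inert") is not None and len(data["inert"]):
        inert_mask = oc.inert_mask_from_regions(grid, data["inert"])
    else:
        inert_mask = oc.select_inert_windows(grid, expressed_genes)
    result = oc.differential_occupancy(
        data["mid1"], data["mid2"], grid,
        inert_mask=inert_mask,
        pseudocount=ocfg["pseudocount"], min_count=ocfg["min_count"],
        alpha=ocfg["alpha"], correction=ocfg["correction"], min_inert=ocfg["min_inert"],
    )
    gio.write_table(result.to_frame(), outdir / "occupancy_windows.tsv")
    smoothed = oc.running_mean(result.fold_change_track, ocfg["smooth_span"], grid.chroms)
    gio.write_bedgraph(grid, smoothed, outdir / "occupancy_foldchange.bedGraph",
                       name="log2_fold_change_smoothed")
    depleted = dm.domains_bed(result, "depleted")
    gio.write_bed(depleted, outdir / "depleted_windows.bed")
    gio.write_bed(dm.domains_bed(result, "enriched"), outdir / "enriched_windows.bed")

    log.info("stage domains (multiscale)")
    mask_fn = (
        (lambda g: oc.inert_mask_from_regions(g, data["inert"]))
        if data.get("inert") is not None and len(data["inert"])
        else (lambda g: oc.select_inert_windows(g, expressed_genes))
    )
    scale_results: dict[int, oc.LLRResult] = {}
    for scale in config["domains"]["scales"]:
        n_windows = sum(-(-l // scale) for l in data["index"].lengths)
        # at coarse scales a small genome cannot supply the full null floor
        floor = max(10, min(ocfg["min_inert"], n_windows // 4))
        scale_results.update(dm.multiscale_domains(
            data["mid1"], data["mid2"], data["index"], scales=(scale,),
            inert_regions_mask=mask_fn,
            pseudocount=ocfg["pseudocount"], min_count=ocfg["min_count"],
            alpha=ocfg["alpha"], correction=config["domains"]["correction"],
            min_inert=floor,
        ))
    scale_rows = []
    for scale, res in scale_results.items():
        labels, counts_ = np.unique(res.label, return_counts=True)
        row = {"scale": scale, "n_windows": res.grid.n}
        row.update({str(l): int(c) for l, c in zip(labels, counts_)})
        scale_rows.append(row)
    gio.write_table(pd.DataFrame(scale_rows).fillna(0), outdir / "multiscale_summary.tsv")

    log.info("stage reposition")
    rcfg = config["reposition"]
    call_frames, event_frames = [], []
    for chrom in data["index"].names:
        m1 = data["mid1"].get(chrom)
        m2 = data["mid2"].get(chrom)
        if m1 is None or m2 is None or len(m1) == 0 or len(m2) == 0:
            continue
        sub = expressed_genes[expressed_genes["chrom"] == chrom]
        if len(sub):
            # single-nucleosome calls are only meaningful where chromatin is
            # positioned; restrict to expressed gene bodies
            keep1 = np.zeros(len(m1), dtype=bool)
            keep2 = np.zeros(len(m2), dtype=bool)
            for gs, ge in zip(sub["start"], sub["end"]):
                keep1 |= (m1 >= gs) & (m1 < ge)
                keep2 |= (m2 >= gs) & (m2 < ge)
            m1, m2 = m1[keep1], m2[keep2]
        if len(m1) == 0 or len(m2) == 0:
            continue
        d1 = nc.dyad_density(m1, rcfg["bandwidth"], chrom)
        d2 = nc.dyad_density(m2, rcfg["bandwidth"], chrom)
        covered = (
            float((sub["end"] - sub["start"]).sum())
            if len(sub)
            else float(data["index"].length(chrom))
        )
        floor = rcfg["min_height_rel"] * len(m1) / covered
        c1 = nc.call_dyads(d1, rcfg["min_separation"], min_height=floor)
        c2 = nc.call_dyads(d2, rcfg["min_separation"], min_height=floor)
        call_frames.append(c1.assign(time="t1"))
        call_frames.append(c2.assign(time="t2"))
        event_frames.append(nc.match_calls(c1, c2, shift_threshold=rcfg["shift_threshold"]))
    calls = pd.concat(call_frames, ignore_index=True) if call_frames else pd.DataFrame()
    events = pd.concat(event_frames, ignore_index=True) if event_frames else pd.DataFrame()
    gio.write_table(calls, outdir / "dyad_calls.tsv")
    gio.write_table(events, outdir / "repositioning_events.tsv")
    if len(events):
        gio.write_bed(nc.unmasked_regions(events), outdir / "unmasked_regions.bed")

    log.info("stage metagene")
    mcfg = config["metagene"]
    gio.write_table(classes.table, outdir / "gene_classes.tsv")
    chrom_lengths = dict(zip(data["index"].names, data["index"].lengths))
    profile_cols = {}
    for cls in ("up", "down", "constitutive"):
        sub = data["genes"][data["genes"]["name"].isin(classes.genes_in(cls))]
        if len(sub) == 0:
            continue
        for label, mids in (("t1", data["mid1"]), ("t2", data["mid2"])):
            prof = mg.scaled_profile(
                mids, sub, body_bins=mcfg["body_bins"], flank=mcfg["flank"],
                flank_bin=mcfg["flank_bin"], chrom_lengths=chrom_lengths,
            )
            profile_cols[f"{cls}_{label}"] = prof.bins
    if profile_cols:
        nbins = len(next(iter(profile_cols.values())))
        flank_bins = mcfg["flank"] // mcfg["flank_bin"]
        axis = np.arange(nbins)
        prof_df = pd.DataFrame({"bin": axis, **profile_cols})
        prof_df["segment"] = np.where(
            axis < flank_bins, "upstream",
            np.where(axis < flank_bins + mcfg["body_bins"], "body", "downstream"),
        )
        gio.write_table(prof_df, outdir / "metagene_profiles.tsv")

    log.info("stage embed/annotate")
    ecfg = config["embed"]
    association = {}
    if data.get("peaks") is not None and len(data["peaks"]):
        emb = dm.overlap_embedded(data["peaks"], depleted, min_frac=ecfg["min_frac"])
        peaks_out = emb.peaks.copy()
        peaks_out["location"] = dm.annotate_location(
            peaks_out, data["genes"], promoter_flank=ecfg["promoter_flank"]
        )
        gio.write_table(
            peaks_out.drop(columns=[c for c in ("planted_inside",) if c in peaks_out]),
            outdir / "peak_embedding.tsv",
        )
        dep_n = int((result.label == "depleted").sum())
        scored = int((~result.low_mask).sum())
        if emb.n_total and dep_n and scored > dep_n:
            odds, p = dm.fisher_association(emb.n_embedded, emb.n_total, dep_n, scored)
            association = {
                "peaks_embedded": emb.n_embedded,
                "peaks_total": emb.n_total,
                "depleted_windows": dep_n,
                "scored_windows": scored,
                "odds_ratio": odds,
                "p_value": p,
            }
            gio.write_table(pd.DataFrame([association]), outdir / "peak_association.tsv")

    contact_summary = {}
    if data.get("contact_table") is not None:
        log.info("stage contacts")
        ccfg = config["contacts"]
        profile = ct.ContactProfile.from_table(
            data["contact_table"], data["contact_chrom"], data["viewpoint"]
        )
        rng = np.random.default_rng(stage_seeds["contacts"])
        sizes = ct.window_ladder(ccfg["wmin"], ccfg["wmax"], ccfg["n_sizes"])
        dres = ct.sliding_enrichment(profile, sizes, n_background=ccfg["n_background"], seed=rng)
        dres = ct.permutation_fdr(profile, dres, n_perm=ccfg["n_perm"], fdr=ccfg["fdr"], seed=rng)
        gio.write_table(
            dres.windows.drop(columns=["i0", "i1"]).assign(significant=dres.significant),
            outdir / "domainogram.tsv",
        )
        sig = ct.significant_windows(dres)
        gio.write_bed(sig.assign(chrom=data["contact_chrom"], name="contact", score=0,
                                 strand=".")[["chrom", "start", "end", "name", "score", "strand"]],
                      outdir / "significant_contacts.bed")
        contact_summary = {
            "n_windows": int((~dres.windows["masked"]).sum()),
            "n_significant": int(dres.significant.sum()),
            "threshold": dres.threshold,
            "background_rate": dres.background_rate,
        }
        try:
            contact_summary.update(
                {f"assoc_{k}": v for k, v in
                 ct.contacts_vs_depletion(dres, depleted, data["contact_chrom"]).items()}
            )
        except ValueError as exc:
            contact_summary["assoc_error"] = str(exc)
        gio.write_table(pd.DataFrame([contact_summary]), outdir / "contact_summary.tsv")

    with open(outdir / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    manifest = {
        "seed": config["seed"],
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report(outdir: str | os.PathLike, make_plots: bool = True) -> pd.DataFrame:
    """One-page summary regenerated from the run directory alone."""
    outdir = Path(outdir)
    rows = []

    def add(metric, value):
        rows.append({"metric": metric, "value": value})

    wfile = outdir / "occupancy_windows.tsv"
    if not wfile.exists():
        raise FileNotFoundError("occupancy stage output missing: occupancy_windows.tsv")
    windows = gio.read_table(wfile)
    for label, n in windows["label"].value_counts().items():
        add(f"windows_{label}", int(n))
    if (outdir / "multiscale_summary.tsv").exists():
        for rec in gio.read_table(outdir / "multiscale_summary.tsv").to_dict("records"):
            for key in ("depleted", "enriched"):
                add(f"scale_{rec['scale']}_{key}", int(rec.get(key, 0)))
    if (outdir / "repositioning_events.tsv").exists():
        ev = gio.read_table(outdir / "repositioning_events.tsv")
        if len(ev):
            for status, n in ev["status"].value_counts().items():
                add(f"nucleosomes_{status}", int(n))
    if (outdir / "gene_classes.tsv").exists():
        gc = gio.read_table(outdir / "gene_classes.tsv")
        for cls, n in gc["gene_class"].value_counts().items():
            add(f"genes_{cls}", int(n))
    if (outdir / "peak_association.tsv").exists():
        assoc = gio.read_table(outdir / "peak_association.tsv").iloc[0]
        add("peaks_embedded", int(assoc["peaks_embedded"]))
        add("peaks_total", int(assoc["peaks_total"]))
        add("peak_odds_ratio", float(assoc["odds_ratio"]))
        add("peak_fisher_p", float(assoc["p_value"]))
    if (outdir / "contact_summary.tsv").exists():
        csum = gio.read_table(outdir / "contact_summary.tsv").iloc[0]
        add("contact_windows", int(csum["n_windows"]))
        add("contact_significant", int(csum["n_significant"]))
    summary = pd.DataFrame(rows)
    gio.write_table(summary, outdir / "summary.tsv")
    if make_plots:
        _plots(outdir, windows)
    return summary


def _plots(outdir: Path, windows: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    ax = axes[0]
    ax.hist(windows.loc[windows["label"] != "low_coverage", "centered"], bins=60,
            color="steelblue")
    ax.set_xlabel("centred log2 ratio ||q||")
    ax.set_ylabel("windows")
    ax.set_title("occupancy statistic")
    ax = axes[1]
    pfile = outdir / "metagene_profiles.tsv"
    if pfile.exists():
        prof = gio.read_table(pfile)
        for col in prof.columns:
            if col in ("bin", "segment"):
                continue
            ax.plot(prof["bin"], prof[col], label=col, lw=1)
        ax.legend(fontsize=7)
        ax.set_xlabel("metagene bin (TSS left)")
        ax.set_ylabel("summed midpoints")
        ax.set_title("metagene profiles")
    fig.tight_layout()
    fig.savefig(outdir / "summary.png", dpi=110)
    plt.close(fig)
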