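"""Orchestration: run enabled analysis stages over a genome and emit the
summary table plus all numeric tracks into an output directory.

The configuration is a YAML (or dict) with keys::

    inputs:
      paths: [genome.gbk]           # or FASTA+GFF3 paths
      format: genbank               # or fasta+gff3
    seed: 0
    stages:                         # each stage may be true/false or a dict
      summarize: true
      composition: {window: 5000, stride: 1000}
      scu: {window: 30, alpha: 1.0e-4, min_run: 3, df: 40}
      skew: {components: [GC, AT], stride: 100}
      pi: {pka_set: embl}
      is_test: {n_perm: 1000, flank: 500}
      map: {markers: markers.tsv, replicon: chr1}

Outputs are deterministic given the config and seed.
"""

from __future__ import annotations

import json
import logging
import os

import pandas as pd
import yaml

from . import __version__
from .composition import composition_profile
from .genome_io import read_genome, write_bed, write_bedgraph, write_feature_table
from .is_context import insertion_site_permutation_test
from .map_integration import calibrate_offset, read_markers
from .proteome_pi import PKA_SETS, proteome_pi
from .scu import assign_reference, detect_islands, island_codon_counts
from .skew import cumulative_disparity, locate_skew_extremum
from .summary import format_summary, start_codon_census, summarize_genome

log = logging.getLogger(__name__)


def _stage_opts(config, name, default_on=True):
    stages = config.get("stages", {})
    val = stages.get(name, default_on)
    if val is False:
        return None
    return val if isinstance(val, dict) else {}


def run_pipeline(config, out_dir) -> str:
    """Run all enabled stages; returns the output directory path.

    ``config`` is a dict or a path to a YAML file.  Raises before any
    stage runs if an input is missing.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    inputs = config.get("inputs", {})
    paths = inputs.get("paths", [])
    if not paths:
        raise ValueError("config names no input paths")
    for p in paths:
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    map_opts = _stage_opts(config, "map", default_on=False)
    if map_opts and not os.path.exists(map_opts["markers"]):
        raise FileNotFoundError(map_opts["markers"])
    seed = int(config.get("seed", 0))
    os.makedirs(out_dir, exist_ok=True)
    logpath = os.path.join(out_dir, "run.json")
    replicons = read_genome(paths, format=inputs.get("format", "genbank"))
    runlog = {"version": __version__, "seed": seed, "config": config,
              "replicons": [r.id for r in replicons]}

    pi_df = None
    opts = _stage_opts(config, "pi")
    if opts is not None:
        pka = PKA_SETS[opts.get("pka_set", "embl")]
        pi_df = proteome_pi(replicons, pka)
        pi_df.to_csv(os.path.join(out_dir, "protein_pi.tsv"), sep="\t",
                     index=False, float_format="%.3f")

    if _stage_opts(config, "summarize") is not None:
        df = summarize_genome(replicons, pi_df)
        format_summary(df).to_csv(os.path.join(out_dir, "summary.tsv"),
                                  sep="\t", index=False)
        census = start_codon_census(replicons)
        with open(os.path.join(out_dir, "start_codons.tsv"), "w") as fh:
            fh.write("codon\tpercent\n")
            for k, v in census.items():
                fh.write(f"{k}\t{v:.1f}\n")
        write_feature_table(replicons, os.path.join(out_dir, "features.tsv"))

    opts = _stage_opts(config, "composition")
    if opts is not None:
        w, s = int(opts.get("window", 5000)), int(opts.get("stride", 1000))
        rows = []
        for r in replicons:
            if r.length < w:
                continue
            prof = composition_profile(r, window=w, stride=s)
            rows.append(dict(replicon=r.id, global_gc=prof.global_gc,
                             coding_gc=prof.coding_gc,
                             noncoding_gc=prof.noncoding_gc,
                             pos1_gc=prof.pos_gc[0] if prof.pos_gc else None,
                             pos2_gc=prof.pos_gc[1] if prof.pos_gc else None,
                             pos3_gc=prof.pos_gc[2] if prof.pos_gc else None,
                             percent_coding=prof.percent_coding))
            write_bedgraph(os.path.join(out_dir, f"{r.id}.gc.bedgraph"),
                           r.id, [p for p, _ in prof.window_gc],
                           [p + w for p, _ in prof.window_gc],
                           [v for _, v in prof.window_gc])
            write_bedgraph(os.path.join(out_dir, f"{r.id}.chi2.bedgraph"),
                           r.id, [p for p, _ in prof.window_chi2],
                           [p + w for p, _ in prof.window_chi2],
                           [v for _, v in prof.window_chi2])
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "composition.tsv"),
                                  sep="\t", index=False, float_format="%.3f")

    opts = _stage_opts(config, "scu")
    if opts is not None:
        window = int(opts.get("window", 30))
        alpha = float(opts.get("alpha", 1e-4))
        min_run = int(opts.get("min_run", 3))
        df_ = int(opts.get("df", 40))
        refs, scans, islands_by = {}, {}, {}
        for r in replicons:
            try:
                scan, islands = detect_islands(r, window=window, df=df_,
                                               alpha=alpha, min_run=min_run)
            except ValueError as e:
                log.warning("scu scan skipped for %s: %s", r.id, e)
                continue
            scans[r.id], islands_by[r.id] = scan, islands
            refs[r.id] = scan.reference
        stat_rows, bed_rows = [], []
        for r in replicons:
            if r.id not in scans:
                continue
            scan = scans[r.id]
            for st in scan.stats:
                stat_rows.append(dict(replicon=r.id, window=st.index,
                                      first_cds=st.cds_range[0],
                                      last_cds=st.cds_range[1],
                                      start=st.span[0] + 1, end=st.span[1],
                                      chi2=st.chi2, df=st.df, p=st.p))
            for isl in islands_by[r.id]:
                if len(refs) >= 2:
                    assign_reference(isl, island_codon_counts(scan, isl),
                                     refs, df=df_, alpha=alpha)
                name = isl.label
                if isl.best_reference:
                    name += f":{isl.best_reference[0]}"
                bed_rows.append((r.id, isl.span[0], isl.span[1], name,
                                 f"{isl.min_p:.3g}"))
        pd.DataFrame(stat_rows).to_csv(
            os.path.join(out_dir, "scu_windows.tsv"), sep="\t", index=False,
            float_format="%.6g")
        write_bed(os.path.join(out_dir, "islands.bed"), bed_rows)

    opts = _stage_opts(config, "skew")
    if opts is not None:
        stride = int(opts.get("stride", 100))
        comps = opts.get("components", ["GC", "AT"])
        ext_rows = []
        for r in replicons:
            for comp in comps:
                curve = cumulative_disparity(r, comp)
                starts = range(0, r.length, stride)
                write_bedgraph(
                    os.path.join(out_dir, f"{r.id}.skew{comp}.bedgraph"),
                    r.id, list(starts),
                    [min(s + stride, r.length) for s in starts],
                    [float(curve.values[s]) for s in starts])
                try:
                    ext = locate_skew_extremum(
                        curve, detrend=r.topology == "circular")
                    ext_rows.append(dict(replicon=r.id, component=comp,
                                         extremum_bp=ext + 1))
                except ValueError:
                    pass
        pd.DataFrame(ext_rows).to_csv(
            os.path.join(out_dir, "skew_extrema.tsv"), sep="\t", index=False)

    opts = _stage_opts(config, "is_test", default_on=False)
    if opts is not None and opts is not False:
        rows = []
        for r in replicons:
            if not r.features_of_kind("IS"):
                continue
            res = insertion_site_permutation_test(
                r, n_perm=int(opts.get("n_perm", 1000)), seed=seed,
                flank=int(opts.get("flank", 500)))
            rows.append(dict(replicon=r.id, p_value=res.p_value,
                             mean_element_gc=res.mean_element_gc,
                             mean_host_gc=res.mean_host_gc,
                             n_permutations=res.n_permutations,
                             seed=res.seed))
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "is_context.tsv"),
                                  sep="\t", index=False, float_format="%.4f")

    if map_opts:
        markers = read_markers(map_opts["markers"])
        cal = calibrate_offset(markers,
                               exclude_names=map_opts.get("exclude", ()))
        cal.markers.to_csv(os.path.join(out_dir, "map_calibration.tsv"),
                           sep="\t", index=False, float_format="%.3f")
        runlog["map_offset_bp"] = cal.offset_bp
        runlog["map_mean_offset_bp"] = cal.mean_offset_bp

    with open(logpath, "w") as fh:
        json.dump(runlog, fh, indent=2, default=str)
    return out_dir
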