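"""End-to-end orchestration of the breakome analysis stages.

A single YAML/dict config drives: (optional) synthetic-data generation,
hotspot calling at three stringencies, the uniform-placement null,
TSS-proximity statistics, SSB-AP overlap and CG context, positional
base composition, and the hotspot-expression association. Every stage
writes TSV/JSON under the output directory and a manifest records the
config snapshot, seeds and output digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as iv
from .expression import (gene_hotspot_status, hierarchical_bins,
                         with_without_comparison)
from .hotspots import (HotspotDefinition, HotspotSet, call_hotspots,
                       hotspot_fraction, pooled_positions)
from .io_core import (BreakSample, ExpressionMatrix, GenomeMask, MappableSpace,
                      TssTable, load_genome, read_breaks)
from .motif import base_fractions, difference_profile, extract_windows, \
    upstream_c_enrichment
from .null_simulation import run_null
from .overlap_ber import (cg_background, cg_context, merged_cohort_hotspots,
                          overlap_odds_ratio, shift_ap_upstream)
from .synthetic_data import SyntheticConfig, SyntheticDataset, generate_all
from .tss_enrichment import (TssIndex, assign_to_tss, bin_odds_ratios, bin_of,
                             density_profile, enrichment_ratio,
                             paired_tissue_test, region_lengths,
                             template_nontemplate_ratio, BIN_LABELS)

logger = logging.getLogger(__name__)

__all__ = ["DEFINITIONS", "run_all", "summarize", "load_config"]

# the three stringencies analysed throughout
DEFINITIONS = {
    "sample_level_d2": HotspotDefinition("sample_level", min_depth=2),
    "sample_shared_d1_s2": HotspotDefinition("sample_shared", min_depth=1, min_samples=2),
    "sample_shared_d2_s2": HotspotDefinition("sample_shared", min_depth=2, min_samples=2),
}
PRIMARY_DEF = "sample_shared_d1_s2"


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _dataset_from_files(inputs: dict) -> SyntheticDataset:
    """Assemble a dataset from user-provided files (no truth attached)."""
    genome = load_genome(inputs["genome"])
    bounds = {c: len(s) for c, s in genome.items()}
    non_repeat = GenomeMask.from_bed(inputs["non_repeat"], "non_repeat")
    polya = GenomeMask.from_bed(inputs["polya_excluded"], "polyA_excluded")
    mappable = MappableSpace(bounds, non_repeat, polya)
    tss = TssTable.from_tsv(inputs["tss"])
    samples = pd.read_csv(inputs["samples"], sep="\t")
    ssb, ap, sample_tissue = [], [], {}
    base = Path(inputs["samples"]).parent
    for row in samples.itertuples(index=False):
        if row.kind == "rna":
            sample_tissue[row.sample_id] = row.tissue
            continue
        path = Path(row.path) if Path(row.path).is_absolute() else base / row.path
        s = read_breaks(path, bounds, sample_id=row.sample_id, tissue=row.tissue)
        (ssb if row.kind == "ssb" else ap).append(s)
    expr = ExpressionMatrix.from_tsv(inputs["expression"], sample_tissue)
    return SyntheticDataset(config=None, genome=genome, non_repeat=non_repeat,
                            polya_excluded=polya, mappable=mappable, tss_table=tss,
                            ssb_samples=ssb, ap_samples=ap, expression=expr,
                            truth=None)


def _mask_filter_all(ds: SyntheticDataset) -> None:
    from .io_core import mask_filter

    combined = ds.mappable.as_mask()
    ds.ssb_samples = [mask_filter(s, combined) for s in ds.ssb_samples]
    ds.ap_samples = [mask_filter(s, combined) for s in ds.ap_samples]


def _hs_to_bed(hs: HotspotSet, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, strand in sorted(hs.positions):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{hs.definition.label}\t1\t{strand}\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_hotspots(ds: SyntheticDataset, outdir: Path) -> dict:
    """All tissue x definition hotspot sets for SSB and AP breaks."""
    hs_dir = outdir / "hotspots"
    hs_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, HotspotSet] = {}
    rows = []
    for kind in ("ssb", "ap"):
        for tissue in ds.tissues:
            samples = ds.samples_of(tissue, kind)
            universe = pooled_positions(samples)
            for name, definition in DEFINITIONS.items():
                hs = call_hotspots(samples, definition)
                key = f"{kind}/{tissue}/{name}"
                results[key] = hs
                frac = hotspot_fraction(hs, universe) if universe else float("nan")
                rows.append({"kind": kind, "tissue": tissue, "definition": name,
                             "n_hotspots": len(hs), "n_positions": len(universe),
                             "fraction": frac,
                             "denominator": "distinct_pooled_positions"})
                _hs_to_bed(hs, hs_dir / f"{kind}_{tissue}_{name}.bed")
        merged = merged_cohort_hotspots([s for s in
                                         (ds.ssb_samples if kind == "ssb"
                                          else ds.ap_samples)])
        results[f"{kind}/merged/{PRIMARY_DEF}"] = merged
        _hs_to_bed(merged, hs_dir / f"{kind}_merged_{PRIMARY_DEF}.bed")
    pd.DataFrame(rows).to_csv(outdir / "hotspot_summary.tsv", sep="\t", index=False)
    return results


def stage_null(ds: SyntheticDataset, outdir: Path, seed: int,
               n_iter: int = 100) -> pd.DataFrame:
    rows, frac_rows = [], []
    for ti, tissue in enumerate(ds.tissues):
        samples = ds.samples_of(tissue, "ssb")
        res = run_null(samples, DEFINITIONS[PRIMARY_DEF], ds.mappable,
                       n_iter=n_iter, rng_seed=seed + ti)
        rows.append({"tissue": tissue, **res.summary(), "seed": seed + ti})
        for it, f in enumerate(res.simulated_fractions):
            frac_rows.append({"tissue": tissue, "iteration": it, "fraction": f})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "null_summary.tsv", sep="\t", index=False)
    pd.DataFrame(frac_rows).to_csv(outdir / "null_fractions.tsv", sep="\t",
                                   index=False)
    return df


def stage_tss(ds: SyntheticDataset, hotspots: dict, outdir: Path) -> dict:
    index = TssIndex(ds.tss_table)
    lengths = region_lengths(index, ds.mappable)
    r_rows, or_frames, tn_rows = [], [], []
    profile_frames = []
    for tissue in ds.tissues:
        sets = {"all_breaks": pooled_positions(ds.samples_of(tissue, "ssb"))}
        for name in DEFINITIONS:
            sets[name] = hotspots[f"ssb/{tissue}/{name}"].positions
        for set_name, positions in sets.items():
            if not positions:
                continue
            asg = assign_to_tss(positions, index, max_distance=5000)
            try:
                er = enrichment_ratio(positions, index, ds.mappable,
                                      assignments=asg, lengths=lengths)
            except ValueError:
                continue
            r_rows.append({"tissue": tissue, "set": set_name, **er})
            if set_name == PRIMARY_DEF:
                ors = bin_odds_ratios(positions, ds.tss_table, ds.mappable,
                                      assignments=asg, lengths=lengths)
                ors.insert(0, "tissue", tissue)
                or_frames.append(ors)
                near = asg[asg["abs_distance"] <= 200].copy()
                near["bin"] = [BIN_LABELS[i] for i in bin_of(near["abs_distance"].values)]
                for lbl in BIN_LABELS:
                    nt = int(((near["bin"] == lbl) &
                              (near["strand_class"] == "template")).sum())
                    nn = int(((near["bin"] == lbl) &
                              (near["strand_class"] == "nontemplate")).sum())
                    tn_rows.append({"tissue": tissue, "bin": lbl, "n_template": nt,
                                    "n_nontemplate": nn,
                                    "ratio": template_nontemplate_ratio(nt, nn)
                                    if nn else float("nan")})
                prof = density_profile(positions, ds.tss_table, ds.mappable,
                                       assignments=asg)
                prof.insert(0, "tissue", tissue)
                profile_frames.append(prof)
    r_df = pd.DataFrame(r_rows)
    r_df.to_csv(outdir / "tss_enrichment.tsv", sep="\t", index=False)
    or_df = pd.concat(or_frames, ignore_index=True) if or_frames else pd.DataFrame()
    or_df.to_csv(outdir / "bin_odds_ratios.tsv", sep="\t", index=False)
    tn_df = pd.DataFrame(tn_rows)
    tn_df.to_csv(outdir / "template_ratios.tsv", sep="\t", index=False)
    if profile_frames:
        pd.concat(profile_frames, ignore_index=True).to_csv(
            outdir / "density_profile.tsv", sep="\t", index=False)
    # paired per-tissue test: hotspot R vs all-break R (one-sided, hotspots higher)
    paired = {}
    if len(ds.tissues) >= 2 and len(r_df):
        piv = r_df.pivot_table(index="tissue", columns="set", values="R")
        if {"all_breaks", PRIMARY_DEF} <= set(piv.columns):
            paired["hotspot_R_gt_background_p"] = paired_tissue_test(
                piv[PRIMARY_DEF].values, piv["all_breaks"].values, "greater")
    (outdir / "tss_paired_tests.json").write_text(json.dumps(paired, indent=1))
    return {"R": r_df, "OR": or_df, "TN": tn_df, "paired": paired,
            "lengths": lengths}


def stage_overlap(ds: SyntheticDataset, hotspots: dict, outdir: Path,
                  lengths: dict) -> pd.DataFrame:
    bounds = {c: len(s) for c, s in ds.genome.items()}
    LG_pos = 2 * ds.mappable.total_bases
    ssb_hs = hotspots[f"ssb/merged/{PRIMARY_DEF}"].positions
    ap_hs = hotspots[f"ap/merged/{PRIMARY_DEF}"].positions
    ssb_all = pooled_positions(ds.ssb_samples)
    ap_all = pooled_positions(ds.ap_samples)
    rows = []
    for set_name, ssb, ap in (("hotspots", ssb_hs, ap_hs),
                              ("all_breaks", ssb_all, ap_all)):
        if not ssb or not ap:
            continue
        for mode in ("direct", "ap_minus_1"):
            ap_use = ap if mode == "direct" else shift_ap_upstream(ap, bounds)
            res = overlap_odds_ratio(ssb, ap_use, mode=mode, LG=LG_pos)
            rows.append({"set": set_name, **res.summary()})
    overlap_df = pd.DataFrame(rows)
    overlap_df.to_csv(outdir / "overlap.tsv", sep="\t", index=False)

    # CG context of SSB hotspots vs exhaustive backgrounds
    mappable_mask = ds.mappable.as_mask()
    tss_windows_200 = {c: iv.merge(iv.as_intervals(
        [(max(0, t - 200), t + 201) for t in grp["tss_pos"]]))
        for c, grp in ds.tss_table.df.groupby("chrom")}
    tss_windows_5 = {c: iv.merge(iv.as_intervals(
        [(max(0, t - 5), t + 6) for t in grp["tss_pos"]]))
        for c, grp in ds.tss_table.df.groupby("chrom")}
    cg_rows = []
    regions = {"genome": None, "tss200": tss_windows_200, "tss5": tss_windows_5}
    index = TssIndex(ds.tss_table)
    asg = assign_to_tss(ssb_hs, index, max_distance=5000) if ssb_hs else None
    for region_name, region in regions.items():
        if region_name == "genome":
            subset = ssb_hs
        else:
            lim = 200 if region_name == "tss200" else 5
            subset = set() if asg is None else set(
                zip(asg[asg["abs_distance"] <= lim]["chrom"],
                    asg[asg["abs_distance"] <= lim]["pos"].astype(int),
                    asg[asg["abs_distance"] <= lim]["strand"]))
        bg = cg_background(ds.genome, mappable_mask, region=region)
        if subset:
            res = cg_context(subset, ds.genome)
            cg_rows.append({"region": region_name, "n_in_cg": res.n_in_cg,
                            "n_total": res.n_total, "fraction": res.fraction,
                            "n_c_bar_g": res.n_c_bar_g, "n_bar_cg": res.n_bar_cg,
                            "background_fraction": bg})
        else:
            cg_rows.append({"region": region_name, "n_in_cg": 0, "n_total": 0,
                            "fraction": float("nan"), "n_c_bar_g": 0,
                            "n_bar_cg": 0, "background_fraction": bg})
    pd.DataFrame(cg_rows).to_csv(outdir / "cg_context.tsv", sep="\t", index=False)
    return overlap_df


def stage_motif(ds: SyntheticDataset, hotspots: dict, outdir: Path,
                seed: int) -> dict:
    from .null_simulation import simulate_breaks

    ssb_hs = hotspots[f"ssb/merged/{PRIMARY_DEF}"].positions
    if not ssb_hs:
        logger.warning("no merged hotspots; motif stage skipped")
        return {}
    rng = np.random.default_rng(seed)
    bg_positions = simulate_breaks(min(len(ssb_hs) * 4, ds.mappable.total_bases),
                                   ds.mappable, rng)
    hot_w = extract_windows(ssb_hs, ds.genome, flank=5)
    bg_w = extract_windows(bg_positions, ds.genome, flank=5)
    mat_hot = base_fractions(hot_w)
    mat_bg = base_fractions(bg_w)
    rows = []
    for label, mat in (("hotspots", mat_hot), ("background", mat_bg)):
        for off in mat.fractions.columns:
            for base in "ACGT":
                rows.append({"set": label, "offset": off, "base": base,
                             "fraction": float(mat.fractions.loc[base, off]),
                             "n": mat.n_sequences})
    pd.DataFrame(rows).to_csv(outdir / "base_fractions.tsv", sep="\t", index=False)
    diff = difference_profile(mat_hot, mat_bg, threshold=0.05)
    diff.to_csv(outdir / "difference_profile.tsv", sep="\t", index=False)
    cstats = upstream_c_enrichment(hot_w, bg_w)
    (outdir / "upstream_c.json").write_text(json.dumps(cstats, indent=1))
    return cstats


def stage_expression(ds: SyntheticDataset, hotspots: dict, outdir: Path,
                     pooling: str = "union") -> dict:
    rows = []
    statuses = {}
    for tissue in ds.tissues:
        status = gene_hotspot_status(hotspots[f"ssb/{tissue}/{PRIMARY_DEF}"],
                                     ds.tss_table)
        statuses[tissue] = status
        for scope in ("either", "template", "nontemplate"):
            cmp_ = with_without_comparison(status, ds.expression, tissue, scope)
            rows.append({"tissue": tissue, "strand_scope": scope,
                         "n_with": cmp_.n_a, "n_without": cmp_.n_b,
                         "median_with": cmp_.median_a, "median_without": cmp_.median_b,
                         "p_value": cmp_.p_value, "testable": cmp_.testable})
    tests_df = pd.DataFrame(rows)
    tests_df.to_csv(outdir / "expression_tests.tsv", sep="\t", index=False)
    members, pair_tests = hierarchical_bins(statuses, ds.expression, pooling=pooling)
    members.to_csv(outdir / "expression_bin_members.tsv", sep="\t", index=False)
    pair_tests.to_csv(outdir / "expression_bin_tests.tsv", sep="\t", index=False)
    return {"tests": tests_df, "members": members, "pair_tests": pair_tests}


# ---------------------------------------------------------------------------
# run-all / summarize
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: dict) -> Path:
    """Execute every stage per the config; returns the output directory."""
    outdir = Path(config.get("outdir", "breakome_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    only = config.get("only_stages")  # None = all stages

    def wanted(name: str) -> bool:
        return only is None or name in only

    timings = {}

    t0 = time.time()
    if config.get("simulate", True):
        syn_cfg = SyntheticConfig(**{**config.get("synthetic", {}),
                                     "rng_seed": seed})
        ds = generate_all(syn_cfg, outdir=outdir / "inputs")
    else:
        ds = _dataset_from_files(config["inputs"])
    _mask_filter_all(ds)
    timings["inputs"] = time.time() - t0

    t0 = time.time()
    hotspots = stage_hotspots(ds, outdir)
    timings["hotspots"] = time.time() - t0

    if wanted("null"):
        t0 = time.time()
        stage_null(ds, outdir, seed=seed + 1000,
                   n_iter=int(config.get("null", {}).get("n_iter", 100)))
        timings["null"] = time.time() - t0

    tss_res = None
    if wanted("tss") or wanted("overlap"):
        t0 = time.time()
        tss_res = stage_tss(ds, hotspots, outdir)
        timings["tss"] = time.time() - t0

    if wanted("overlap"):
        t0 = time.time()
        stage_overlap(ds, hotspots, outdir, tss_res["lengths"])
        timings["overlap"] = time.time() - t0

    if wanted("motif"):
        t0 = time.time()
        stage_motif(ds, hotspots, outdir, seed=seed + 2000)
        timings["motif"] = time.time() - t0

    if wanted("expression"):
        t0 = time.time()
        stage_expression(ds, hotspots, outdir,
                         pooling=config.get("expression", {}).get("pooling", "union"))
        timings["expression"] = time.time() - t0

    digests = {str(p.relative_to(outdir)): _digest(p)
               for p in sorted(outdir.rglob("*")) if p.is_file()}
    manifest = {"config": {k: v for k, v in config.items()},
                "seed": seed, "timings": timings, "digests": digests,
                "stages": list(timings),
                "synthetic_config": asdict(ds.config) if ds.config else None}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return outdir


def summarize(outdir) -> list[Path]:
    """Collect stage outputs into one report file per analysis theme."""
    outdir = Path(outdir)
    reports = []

    def _copy(src_names: list[str], dest: str):
        frames = []
        for name in src_names:
            p = outdir / name
            if p.exists():
                frames.append(pd.read_csv(p, sep="\t"))
            else:
                logger.warning("summarize: missing %s", name)
        if frames:
            path = outdir / dest
            pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
            reports.append(path)

    _copy(["hotspot_summary.tsv", "null_summary.tsv"], "report_hotspot_null.tsv")
    _copy(["tss_enrichment.tsv"], "report_tss_enrichment.tsv")
    _copy(["bin_odds_ratios.tsv", "template_ratios.tsv"], "report_bin_or.tsv")
    _copy(["expression_tests.tsv", "expression_bin_tests.tsv"],
          "report_expression.tsv")
    _copy(["base_fractions.tsv", "difference_profile.tsv"], "report_motif.tsv")
    _copy(["overlap.tsv", "cg_context.tsv"], "report_overlap_cg.tsv")
    return reports
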