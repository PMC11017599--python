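"""Planted-structure generator: construction guarantees and brute-force
recovery of the configured parameters from the emitted files."""

import numpy as np
import pytest

from breakome.io_core import load_genome
from breakome.overlap_ber import shift_ap_upstream
from breakome.synthetic_data import (SyntheticConfig, generate_all,
                                     generate_genome)
from breakome.tss_enrichment import TssIndex


def small_cfg(**kw):
    base = dict(genome_length=200_000, n_genes=20, breaks_per_sample=2000,
                hot_pool_size=100, rng_seed=5)
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenome:
    def test_zero_repeats_full_non_repeat_mask(self):
        cfg = small_cfg(repeat_fraction=0.0)
        genome, _, non_repeat, _ = generate_genome(cfg, np.random.default_rng(0))
        for chrom, seq in genome.items():
            ivs = non_repeat.intervals(chrom)
            assert ivs.tolist() == [[0, len(seq)]]

    def test_gc_content_recovered(self):
        cfg = small_cfg(gc_content=0.5, cpg_island_at_tss=False, polya_rate=0.0)
        genome, _, _, _ = generate_genome(cfg, np.random.default_rng(1))
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        se = np.sqrt(0.25 / len(seq))
        assert abs(gc - 0.5) <= 3 * se

    def test_repeat_fraction_approximate(self):
        cfg = small_cfg(repeat_fraction=0.3)
        genome, _, non_repeat, _ = generate_genome(cfg, np.random.default_rng(2))
        L = sum(len(s) for s in genome.values())
        frac_nr = non_repeat.total_length() / L
        assert 0.55 <= frac_nr <= 0.85  # ~0.70 with block granularity

    def test_cpg_islands_enrich_tss_windows(self):
        cfg = small_cfg(cpg_island_at_tss=True)
        genome, tss, _, _ = generate_genome(cfg, np.random.default_rng(3))
        seq = genome["chr1"]

        def cg_freq(s):
            return sum(1 for i in range(len(s) - 1) if s[i:i + 2] == "CG") / len(s)

        tss_cg = np.mean([cg_freq(seq[max(0, t - 200):t + 200])
                          for t in tss.df["tss_pos"]])
        assert tss_cg > 2 * cg_freq(seq)


class TestReproducibilityAndSupport:
    def test_fixed_seed_byte_identical_files(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_all(small_cfg(), outdir=a)
        generate_all(small_cfg(), outdir=b)
        files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel

    def test_emitted_breaks_lie_in_mappable_space(self, tiny_ds):
        for s in tiny_ds.ssb_samples + tiny_ds.ap_samples:
            for chrom, grp in s.df.groupby("chrom"):
                assert tiny_ds.mappable.is_mappable(chrom, grp["pos"].values).all()

    def test_written_bundle_loads_back(self, tmp_path):
        ds = generate_all(small_cfg(), outdir=tmp_path / "d")
        genome = load_genome(tmp_path / "d" / "genome.fa")
        assert genome == ds.genome


class TestParameterRecoveryFromFiles:
    def test_realized_hot_fraction(self, tiny_ds):
        """Depth mass at pool positions recovers h = events/pool share."""
        cfg = tiny_ds.config
        pool = set(tiny_ds.truth.hot_pool)
        h_hat = []
        extra_depth = 1 / cfg.depth_geometric_p - 1  # E[geometric - 1]
        for s in tiny_ds.ssb_samples:
            at_pool = s.df[[tuple(r) in pool for r in
                            zip(s.df["chrom"], s.df["pos"], s.df["strand"])]]
            events = at_pool["depth"].sum() - extra_depth * len(at_pool)
            h_hat.append(events / cfg.breaks_per_sample)
        assert abs(np.mean(h_hat) - cfg.hot_fraction) < 0.2 * cfg.hot_fraction

    def test_realized_template_bias(self, tiny_ds):
        """Template:nontemplate position counts near TSSs recover beta."""
        index = TssIndex(tiny_ds.tss_table)
        t = nt = 0
        for s in tiny_ds.ssb_samples:
            for chrom, grp in s.df.groupby("chrom"):
                d, gs = index.nearest_arrays(chrom, grp["pos"].values)
                near = np.abs(d) <= 200
                is_t = (grp["strand"].values != gs) & near
                t += int(is_t.sum())
                nt += int((near & ~is_t).sum())
        beta = tiny_ds.config.template_bias
        assert abs(t / nt - beta) < 0.25 * beta

    def test_ap_purine_bias_realized(self, tiny_ds):
        pur = tot = 0
        for s in tiny_ds.ap_samples[:3]:
            for r in s.records():
                base = tiny_ds.genome[r.chrom][r.pos]
                if r.strand == "-":
                    base = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
                pur += base in "AG"
                tot += 1
        assert pur / tot > 0.6  # configured target 0.7, pool dilutes slightly

    def test_couplings_verifiable_direct_mode(self, tiny_ds):
        assert tiny_ds.config.ap_coupling_mode == "direct"
        assert len(tiny_ds.truth.couplings) > 0
        for ssb, ap in tiny_ds.truth.couplings:
            assert tuple(ssb) == tuple(ap)
        ap_pool = set(map(tuple, tiny_ds.truth.ap_pool))
        assert all(tuple(ap) in ap_pool for _, ap in tiny_ds.truth.couplings)

    def test_couplings_verifiable_offset_mode(self):
        ds = generate_all(small_cfg(ap_coupling_mode="offset"))
        assert len(ds.truth.couplings) > 0
        for ssb, ap in ds.truth.couplings:
            assert shift_ap_upstream({tuple(ap)}) == {tuple(ssb)}


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"hot_fraction": 1.5},
        {"tss_enrichment_factor": 0.5},
        {"ap_coupling_mode": "sideways"},
        {"genome_length": 10_000, "n_genes": 100},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)


class TestExpressionGenerator:
    def test_effect_multiplies_flagged_genes(self):
        from breakome.synthetic_data import generate_expression
        import pandas as pd
        flags = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)],
            "has_template": [i < 100 for i in range(200)],
            "bin_template": ["5" if i < 100 else "none" for i in range(200)],
            "has_nontemplate": False, "bin_nontemplate": "none"})
        cfg = small_cfg(expression_effect=4.0, expression_noise=0.05)
        e = generate_expression(cfg, flags, np.random.default_rng(9))
        med_with = e.tpm.iloc[:100].median(axis=1).median()
        med_without = e.tpm.iloc[100:].median(axis=1).median()
        assert med_with > 2 * med_without
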