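"""Simulator invariants: determinism, track consistency, allele structure."""

import numpy as np
import pytest

from tprt_detect.sim import (
    EventSpec,
    SimConfig,
    default_event_panel,
    simulate_genome,
    simulate_reads,
    simulate_tprt_insertions,
)


def _run(seed=4, n_events=12):
    cfg = SimConfig(seed=seed, ref_len_bp=300_000, n_samples=6, n_tumors=2)
    cfg.events = default_event_panel(cfg, n_events)
    genome = simulate_genome(cfg)
    calls, truth, placed = simulate_tprt_insertions(cfg, genome)
    return cfg, genome, calls, truth, placed


class TestSimulateGenome:
    def test_same_seed_identical_output(self):
        g1 = simulate_genome(SimConfig(seed=9, ref_len_bp=150_000))
        g2 = simulate_genome(SimConfig(seed=9, ref_len_bp=150_000))
        assert g1.ref == g2.ref
        assert g1.repeats.records == g2.repeats.records

    def test_repeat_records_match_sequence(self):
        g = simulate_genome(SimConfig(seed=9, ref_len_bp=150_000))
        from tprt_detect._dna import revcomp

        for chrom, start, end, label, _ in g.repeats.records:
            cls, strand = label.split("|")[0], label.split("|")[1]
            if cls != "SINE":
                continue
            copy = g.ref[chrom][start:end]
            alu = g.library["AluY"].sequence
            assert copy == (alu if strand == "+" else revcomp(alu))
            assert 281 <= end - start <= 343

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, repeat_fraction_by_class={"SINE": 0.7, "LINE": 0.5})


class TestSimulateInsertions:
    def test_truth_rows_cover_all_events(self):
        cfg, _, calls, truth, placed = _run()
        assert len(truth) == len(cfg.events)
        ins_truth = truth[truth.sv_type == "INS"]
        assert len(placed) == len(ins_truth)
        # every carrier holds a per-sample call
        n_calls = sum(len(v) for v in calls.values())
        assert n_calls == sum(len(s.carrier_samples) for s in cfg.events)

    def test_vcf_sequence_reconstructs_haplotype(self):
        _, genome, _, truth, placed = _run()
        ref = genome.ref["chrS"]
        for ev in placed:
            t = truth.set_index("event_id").loc[ev.spec.event_id]
            pos = ev.call_template.pos
            w0, w1 = ev.hap_window
            if t.tsd_kind == "deletion":
                # the VCF seq excludes the deleted target bases
                assert ev.haplotype == ref[w0:pos] + ev.call_template.seq + ref[pos + t.tsd_len: w1]
            else:
                assert ev.haplotype == ref[w0:pos] + ev.call_template.seq + ref[pos:w1]

    def test_en_motif_planted_at_nick(self):
        from tprt_detect.te_annotate import detect_en_cut, en_context

        _, genome, _, truth, placed = _run(n_events=20)
        ref = genome.ref["chrS"]
        for ev in placed:
            up, down = en_context(ref, ev.nick_pos, ev.spec.strand)
            assert detect_en_cut(up, down) == ev.spec.en_motif

    def test_events_well_separated(self):
        _, _, _, truth, placed = _run(n_events=20)
        pos = sorted(p.call_template.pos for p in placed)
        assert min(b - a for a, b in zip(pos, pos[1:])) > 10


class TestSimulateReads:
    def test_same_seed_identical_reads(self):
        cfg, genome, calls, truth, placed = _run()
        r1 = simulate_reads(genome, placed, cfg, depth=6, error_rate=0.02, seed=5)
        r2 = simulate_reads(genome, placed, cfg, depth=6, error_rate=0.02, seed=5)
        assert r1.reads == r2.reads

    def test_somatic_alleles_confined_to_tumor(self):
        cfg, genome, calls, truth, placed = _run()
        rs = simulate_reads(genome, placed, cfg, depth=6)
        for ev in placed:
            if ev.spec.zygosity != "somatic":
                continue
            for sample in cfg.samples:
                entry = rs.reads.get((ev.spec.event_id, sample), {})
                if sample in ev.spec.carrier_samples:
                    assert entry["ins"], "tumor carrier must have insertion reads"
                else:
                    assert not entry.get("ins")
                assert entry.get("ref"), "every sample has reference reads"

    def test_error_free_reads_are_substrings(self):
        cfg, genome, calls, truth, placed = _run()
        rs = simulate_reads(genome, placed, cfg, depth=4, error_rate=0.0)
        ev = placed[0]
        sample = ev.spec.carrier_samples[0]
        for _, seq in rs.reads[(ev.spec.event_id, sample)]["ins"]:
            assert seq in ev.haplotype

    def test_heterozygous_allele_balance(self):
        cfg, genome, calls, truth, placed = _run()
        rs = simulate_reads(genome, placed, cfg, depth=20)
        ev = placed[0]
        sample = ev.spec.carrier_samples[0]
        entry = rs.reads[(ev.spec.event_id, sample)]
        assert len(entry["ins"]) == len(entry["ref"]) == 10


class TestEventSpecValidation:
    def test_inversion_limited_to_tprt_families(self):
        with pytest.raises(ValueError):
            EventSpec("e", "ERV", "somatic", ["T0"], invert=True)

    def test_tsd_window_enforced(self):
        with pytest.raises(ValueError):
            EventSpec("e", "Alu", "somatic", ["T0"], tsd_kind="duplication", tsd_len=4)
        with pytest.raises(ValueError):
            EventSpec("e", "Alu", "somatic", ["T0"], tsd_kind="duplication", tsd_len=26)
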