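import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hlacapseq.genotype import GenotypeCall
from hlacapseq.pipeline import load_paired_fastq
from hlacapseq.quantify import (
    AllZeroSampleError,
    PhaseStatus,
    build_dataset,
    classify_phase,
    count_in_phase,
    count_pair,
    locus_set,
    normalize_to_million,
    quantify_sample,
    standardize_by_size,
)
from hlacapseq.reference import AlleleName, Locus, ReferenceSet
from hlacapseq.simulate import (
    SimConfig,
    emit_reads,
    reverse_complement,
    synthesize_panel,
)

from conftest import make_allele, make_truth


def het_call(locus, ref_a, ref_b):
    return GenotypeCall(locus, (ref_a.name, ref_b.name), "heterozygous")


def mutate(seq, pos, to=None):
    s = list(seq)
    s[pos] = to or {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
    return "".join(s)


class TestClassifyPhase:
    def _pair(self, exons_a, exons_b, locus=Locus.A, exon_ids=(2, 3)):
        a = make_allele(locus=locus, f1=1, exons=exons_a, exon_ids=exon_ids)
        b = make_allele(locus=locus, f1=2, exons=exons_b, exon_ids=exon_ids)
        panel = ReferenceSet([a, b])
        return het_call(locus, a, b), panel

    def test_differs_in_every_exon_is_completely_phased(self):
        call, panel = self._pair(("ACGT", "TTGG"), ("AGGT", "TTCG"))
        assert classify_phase(call, panel) is PhaseStatus.COMPLETELY_PHASED

    def test_differs_in_one_exon_only_is_partially_phased(self):
        call, panel = self._pair(("ACGT", "TTGG"), ("AGGT", "TTGG"))
        assert classify_phase(call, panel) is PhaseStatus.PARTIALLY_PHASED

    def test_identical_windows_behave_as_homozygous(self):
        call, panel = self._pair(("ACGT", "TTGG"), ("ACGT", "TTGG"))
        assert classify_phase(call, panel) is PhaseStatus.HOMOZYGOUS

    def test_hemizygous_drb_paralog(self):
        ref = make_allele(locus=Locus.DRB4, exons=("ACGT",), exon_ids=(2,))
        call = GenotypeCall(Locus.DRB4, (ref.name,), "hemizygous")
        assert classify_phase(call, ReferenceSet([ref])) is PhaseStatus.HEMIZYGOUS

    def test_partial_reference_is_partially_phased(self):
        a = make_allele(f1=1, exons=("ACGT",), exon_ids=(2,))  # missing exon 3
        b = make_allele(f1=2, exons=("AGGT", "TTGG"))
        call, panel = het_call(Locus.A, a, b), ReferenceSet([a, b])
        assert classify_phase(call, panel) is PhaseStatus.PARTIALLY_PHASED


class TestCountInPhase:
    def test_read_matching_both_alleles_counts_for_neither(self):
        shared = "ACGTACGTAC"
        a = make_allele(locus=Locus.DQB1, f1=1, exons=(shared + "A" + "GGTTGGTTGG",), exon_ids=(2,))
        b = make_allele(locus=Locus.DQB1, f1=2, exons=(shared + "C" + "GGTTGGTTGG",), exon_ids=(2,))
        panel = ReferenceSet([a, b])
        call = het_call(Locus.DQB1, a, b)
        counts = count_in_phase([("r1", shared)], call, panel)
        assert counts == {a.name.render(): 0, b.name.render(): 0}
        counts = count_in_phase([("r2", shared + "A")], call, panel)
        assert counts[a.name.render()] == 1 and counts[b.name.render()] == 0

    def test_split_mode_shares_ambiguous_reads(self):
        shared = "ACGTACGTAC"
        a = make_allele(locus=Locus.DQB1, f1=1, exons=(shared + "AGG",), exon_ids=(2,))
        b = make_allele(locus=Locus.DQB1, f1=2, exons=(shared + "CGG",), exon_ids=(2,))
        panel = ReferenceSet([a, b])
        counts = count_in_phase(
            [("r1", shared)], het_call(Locus.DQB1, a, b), panel, split_ambiguous=True
        )
        assert counts == {a.name.render(): 0.5, b.name.render(): 0.5}

    def test_requires_completely_phased_pair(self):
        a = make_allele(f1=1, exons=("ACGT", "TTGG"))
        b = make_allele(f1=2, exons=("AGGT", "TTGG"))
        panel = ReferenceSet([a, b])
        with pytest.raises(ValueError, match="completely phased"):
            count_in_phase([], het_call(Locus.A, a, b), panel)

    def test_counts_match_brute_force_oracle(self, rng):
        panel = synthesize_panel([Locus.DPA1], 2, 3, seed=23)
        ra, rb = panel.by_locus(Locus.DPA1)
        reads = []
        for i in range(200):
            src = (ra, rb)[int(rng.integers(2))]
            n = int(rng.integers(30, 80))
            pos = int(rng.integers(0, len(src.sequence) - n))
            seq = src.sequence[pos : pos + n]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            if rng.random() < 0.2:
                seq = mutate(seq, int(rng.integers(len(seq))))
            reads.append((f"r{i}", seq))

        def occurs(seq, ref):
            return seq in ref.sequence or reverse_complement(seq) in ref.sequence

        def window_hit(seq, ref):
            ws, we = ref.exon_interval(2)
            for oriented in (seq, reverse_complement(seq)):
                start = ref.sequence.find(oriented)
                while start != -1:
                    if start < we and start + len(oriented) > ws:
                        return True
                    start = ref.sequence.find(oriented, start + 1)
            return False

        exp_a = exp_b = 0
        for _, seq in reads:
            in_a, in_b = occurs(seq, ra), occurs(seq, rb)
            if in_a and in_b:
                continue
            if in_a and window_hit(seq, ra):
                exp_a += 1
            elif in_b and window_hit(seq, rb):
                exp_b += 1
        ca, cb, _ = count_pair(reads, ra, rb)
        assert (ca, cb) == (exp_a, exp_b)

    def test_balanced_alleles_within_binomial_bounds(self, tmp_path):
        # the independent sampling unit is the read pair (mates of one
        # fragment are correlated), so the binomial(n, 0.5) bound is applied
        # to deduplicated pair-level assignments
        from hlacapseq.pipeline import pair_id
        from hlacapseq.quantify import assign_in_phase

        panel = synthesize_panel([Locus.B], 2, 3, seed=29)
        a1, a2 = sorted(panel.names)
        ra, rb = panel[a1], panel[a2]
        for seed in range(20):
            truth = make_truth([("S0", "B", 1, a1, 1.0), ("S0", "B", 2, a2, 1.0)])
            cfg = SimConfig(n_samples=1, depth=2000, error_rate=0.0, seed=seed)
            fastqs = emit_reads(truth, panel, cfg, tmp_path / str(seed))
            reads = load_paired_fastq(*fastqs["S0"])
            pair_labels = {}
            for rid, label in assign_in_phase(reads, ra, rb):
                if label in ("x", "y"):
                    pair_labels.setdefault(pair_id(rid), set()).add(label)
            ca = sum(1 for ls in pair_labels.values() if ls == {"x"})
            cb = sum(1 for ls in pair_labels.values() if ls == {"y"})
            n = ca + cb
            assert abs(ca - n / 2) <= 3 * np.sqrt(n * 0.25) + 1


class TestNormalization:
    @pytest.mark.parametrize(
        "raw, size, expected",
        [(546, 546, 1.0), (0, 270, 0.0), (1000, 270, 1000 / 270)],
    )
    def test_standardize_examples(self, raw, size, expected):
        assert standardize_by_size(raw, size) == pytest.approx(expected)

    def test_zero_target_size_is_an_error(self):
        with pytest.raises(ValueError):
            standardize_by_size(10, 0)

    def test_normalize_examples(self):
        assert list(normalize_to_million([1, 1, 2])) == [250_000, 250_000, 500_000]
        assert list(normalize_to_million([7.3])) == [1_000_000]

    def test_all_zero_sample_is_flagged(self):
        with pytest.raises(AllZeroSampleError):
            normalize_to_million([0.0, 0.0])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=30)
    )
    @settings(max_examples=200, deadline=None)
    def test_normalized_sum_is_one_million(self, values):
        out = normalize_to_million(values)
        assert abs(out.sum() - 1_000_000) <= 1e-9 * 1_000_000

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=2, max_size=10),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_ratio_preservation(self, values, c):
        base = normalize_to_million(values)
        scaled = normalize_to_million([v * c for v in values])
        assert np.allclose(base, scaled, rtol=1e-9)
        # normalized ratios equal size-standardized ratios
        assert np.allclose(
            base / base[0], np.asarray(values) / values[0], rtol=1e-9
        )


def _simulated_quants(tmp_path, loci, n_samples=4, depth=400, seed=31):
    from hlacapseq.pipeline import genotype_sample
    from hlacapseq.simulate import simulate_expression, simulate_genotypes

    panel = synthesize_panel(loci, 3, 3, seed=seed)
    geno = simulate_genotypes(panel, n_samples, seed=seed)
    cfg = SimConfig(n_samples=n_samples, depth=depth, error_rate=0.0, seed=seed)
    truth = simulate_expression(geno, cfg)
    fastqs = emit_reads(truth, panel, cfg, tmp_path)
    quants = []
    for sample_id, (r1, r2) in fastqs.items():
        reads = load_paired_fastq(r1, r2)
        calls, _ = genotype_sample(reads, panel, min_unique_support=5)
        quants.append(quantify_sample(sample_id, reads, calls, panel))
    return quants


class TestBuildDataset:
    def test_locus_set_definitions(self):
        assert locus_set(1).loci == frozenset(Locus)
        assert locus_set(2).loci == {Locus.A, Locus.B, Locus.C}
        assert Locus.DRB3 not in locus_set(3).loci
        assert Locus.DRB3 in locus_set(4).loci
        assert not locus_set(2).drb345_included and locus_set(4).drb345_included
        with pytest.raises(ValueError):
            locus_set(5)

    def test_class1_simulation_gives_six_rows_per_sample(self, tmp_path):
        quants = _simulated_quants(tmp_path, [Locus.A, Locus.B, Locus.C])
        table = build_dataset(quants, locus_set(2))
        per_sample = table.groupby("sample_id").size()
        for sq in quants:
            phased = [
                l for l, s in sq.locus_status.items()
                if s is PhaseStatus.COMPLETELY_PHASED
            ]
            if len(phased) == 3:
                assert per_sample[sq.sample_id] == 6

    def test_per_sample_sums_are_one_million(self, tmp_path):
        quants = _simulated_quants(
            tmp_path, [Locus.A, Locus.DRB1, Locus.DRB3, Locus.DRB4], depth=600
        )
        for set_id in (1, 2, 3, 4):
            table = build_dataset(quants, locus_set(set_id))
            if len(table) == 0:
                continue
            sums = table.groupby("sample_id")["normalized_reads"].sum()
            assert np.allclose(sums, 1_000_000, rtol=1e-9)

    def test_hemizygous_drb_sample_excluded_from_sets_1_and_4_only(self):
        # hand-build: phased class I + class II loci, single DRB4 allele
        quants = []
        panel_refs = {}
        for locus, f1s in ((Locus.A, (1, 2)), (Locus.DQB1, (1, 2)), (Locus.DRB4, (1,))):
            for f1 in f1s:
                exons = ("ACGT" * 10,) if locus is not Locus.A else ("ACGT" * 10, "GGTT" * 10)
                ids = (2,) if locus is not Locus.A else (2, 3)
                seq = mutate("ACGT" * 10, f1)
                ref = make_allele(
                    locus=locus,
                    f1=f1,
                    exons=(seq,) if locus is not Locus.A else (seq, "GGTT" * 10),
                    exon_ids=ids,
                )
                panel_refs[(locus, f1)] = ref
        from hlacapseq.quantify import AlleleQuant, SampleQuant

        sq = SampleQuant("S0")
        sq.locus_status = {
            Locus.A: PhaseStatus.COMPLETELY_PHASED,
            Locus.DQB1: PhaseStatus.COMPLETELY_PHASED,
            Locus.DRB4: PhaseStatus.HEMIZYGOUS,
        }
        sq.drb_group_status = PhaseStatus.HEMIZYGOUS
        for (locus, f1), ref in panel_refs.items():
            if locus is Locus.DRB4:
                continue
            sq.counts.append(AlleleQuant(ref.name.render(), locus, 100 + f1, 40))
        quants = [sq]
        assert build_dataset(quants, locus_set(1)).empty
        assert build_dataset(quants, locus_set(4)).empty
        assert set(build_dataset(quants, locus_set(2))["locus"]) == {"A"}
        assert set(build_dataset(quants, locus_set(3))["locus"]) == {"DQB1"}

    def test_excluded_categories_never_appear(self, tmp_path):
        quants = _simulated_quants(
            tmp_path, [Locus.A, Locus.DRB1, Locus.DRB3, Locus.DRB4], depth=600, seed=37
        )
        allowed = {
            sq.sample_id: {
                l.value
                for l, s in sq.locus_status.items()
                if s is PhaseStatus.COMPLETELY_PHASED
            }
            | ({"DRB3", "DRB4", "DRB5"} if sq.drb_group_status is PhaseStatus.COMPLETELY_PHASED else set())
            for sq in quants
        }
        for set_id in (1, 2, 3, 4):
            table = build_dataset(quants, locus_set(set_id))
            for row in table.itertuples(index=False):
                assert row.locus in allowed[row.sample_id]


class TestDrbParalogGroup:
    def test_cross_paralog_pair_is_phased_and_counted(self, tmp_path):
        panel = synthesize_panel([Locus.DRB3, Locus.DRB4], 2, 3, seed=41)
        a3 = sorted(r.name.render() for r in panel.by_locus(Locus.DRB3))[0]
        a4 = sorted(r.name.render() for r in panel.by_locus(Locus.DRB4))[0]
        truth = make_truth(
            [("S0", "DRB3", 1, a3, 1.0), ("S0", "DRB4", 2, a4, 1.0)]
        )
        cfg = SimConfig(n_samples=1, depth=400, error_rate=0.0, seed=2)
        fastqs = emit_reads(truth, panel, cfg, tmp_path)
        reads = load_paired_fastq(*fastqs["S0"])
        from hlacapseq.pipeline import genotype_sample

        calls, _ = genotype_sample(reads, panel, min_unique_support=5)
        sq = quantify_sample("S0", reads, calls, panel)
        assert sq.drb_group_status is PhaseStatus.COMPLETELY_PHASED
        counted = {q.allele for q in sq.counts}
        assert counted == {a3, a4}
        assert all(q.raw_reads > 0 for q in sq.counts)
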