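"""Domain/IDR architecture statistics and cross-species conservation."""

import numpy as np
import pytest

import utag.architecture as ar
import utag.synthetic as syn
from utag.errors import ContractError, UndefinedCompositionError


def _protein(pid, seq, domains=(), disorder=None, species="sp"):
    if disorder is None:
        disorder = np.full(len(seq), 0.9)
    return ar.ProteinArchitecture(
        protein_id=pid, species=species, sequence=seq,
        domains=list(domains), disorder=np.asarray(disorder, float),
    )


class TestIdrMask:
    def test_no_domains_all_disordered(self):
        p = _protein("p", "A" * 30)
        assert ar.idr_mask(p).all()

    def test_all_residues_inside_domains(self):
        p = _protein("p", "A" * 30, domains=[("RRM", 1, 30)])
        assert not ar.idr_mask(p).any()

    def test_cutoff_is_strict(self):
        p = _protein("p", "A" * 10, disorder=np.full(10, 0.5))
        assert not ar.idr_mask(p).any()
        p2 = _protein("p", "A" * 10, disorder=np.full(10, 0.5 + 1e-9))
        assert ar.idr_mask(p2).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            _protein("p", "AAAA", disorder=np.ones(3))


class TestRegionFractions:
    def test_hand_construction(self):
        p = _protein("p", "A" * 100, domains=[("RRM", 1, 27)])
        f_dom, f_idr, f_other = ar.region_fractions(p)
        assert (f_dom, f_idr, f_other) == pytest.approx((0.27, 0.73, 0.0))

    def test_residue_by_residue_enumeration(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        dis = np.array([0.9, 0.1] * 10)
        p = _protein("p", seq, domains=[("KH", 3, 7)], disorder=dis)
        dom_manual = sum(1 for i in range(20) if 3 <= i + 1 <= 7)
        idr_manual = sum(
            1 for i in range(20) if not (3 <= i + 1 <= 7) and dis[i] > 0.5
        )
        f_dom, f_idr, f_other = ar.region_fractions(p)
        assert f_dom == pytest.approx(dom_manual / 20)
        assert f_idr == pytest.approx(idr_manual / 20)

    def test_fractions_sum_to_one_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = int(rng.integers(30, 200))
            n_dom = int(rng.integers(0, 3))
            doms = []
            for _ in range(n_dom):
                s = int(rng.integers(1, L))
                e = int(rng.integers(s, L + 1))
                doms.append(("D", s, e))
            p = _protein("p", "A" * L, domains=doms, disorder=rng.random(L))
            assert sum(ar.region_fractions(p)) == pytest.approx(1.0)

    def test_overlapping_domains_counted_once(self):
        p = _protein(
            "p", "A" * 100, domains=[("RRM", 1, 50), ("RRM", 30, 60)]
        )
        f_dom, _, _ = ar.region_fractions(p)
        assert f_dom == pytest.approx(0.60)


class TestDomainSpanFraction:
    def test_full_span(self):
        p = _protein("p", "A" * 40, domains=[("RRM", 1, 40)])
        assert ar.domain_span_fraction(p) == pytest.approx(1.0)

    def test_first_to_last_extent(self):
        p = _protein(
            "p", "A" * 100, domains=[("RRM", 10, 19), ("KH", 90, 99)]
        )
        assert ar.domain_span_fraction(p) == pytest.approx(0.90)

    def test_single_small_domain(self):
        p = _protein("p", "A" * 100, domains=[("RRM", 40, 49)])
        assert ar.domain_span_fraction(p) == pytest.approx(0.10)

    def test_no_domains_missing(self):
        assert ar.domain_span_fraction(_protein("p", "A" * 50)) is None


class TestAAComposition:
    def test_single_residue_type(self):
        p = _protein("p", "AAAA")
        comp = ar.aa_composition(p, np.ones(4, bool))
        assert comp["A"] == 1.0 and comp.drop("A").sum() == 0.0

    def test_uniform_over_four(self):
        p = _protein("p", "ACDE")
        comp = ar.aa_composition(p, np.ones(4, bool))
        assert all(comp[aa] == 0.25 for aa in "ACDE")

    def test_sums_to_one(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(ar.AA_ALPHABET), size=60))
        p = _protein("p", seq)
        assert ar.aa_composition(p).sum() == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        p = _protein("p", "ACDE")
        with pytest.raises(UndefinedCompositionError):
            ar.aa_composition(p, np.zeros(4, bool))


class TestCompositionCorrelation:
    def test_identical_compositions_correlate_perfectly(self):
        p1 = _protein("p1", "ACDEACDE" * 5)
        p2 = _protein("p2", "ACDEACDE" * 3)
        cm = ar.composition_correlation([p1, p2])
        assert cm.correlations.loc["p1", "p2"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        prots = [
            _protein(f"p{i}", "".join(rng.choice(list(ar.AA_ALPHABET), 80)))
            for i in range(4)
        ]
        cm = ar.composition_correlation(prots)
        c = cm.correlations
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)

    def test_ordering_by_similarity_to_tf_mean(self):
        tf = _protein("tf", "DDDDEEEE" * 10)
        close = _protein("close", "DDDEEEEK" * 10)
        far = _protein("far", "LLLLVVVV" * 10, disorder=np.full(80, 0.9))
        cm = ar.composition_correlation(
            [far, close, tf], group_labels={"tf": "TF"}
        )
        assert cm.order.index("close") < cm.order.index("far")

    def test_hand_compositions_match_direct_formula(self):
        p1 = _protein("p1", "AACD")
        p2 = _protein("p2", "ACCD")
        p3 = _protein("p3", "ACDD")
        cm = ar.composition_correlation([p1, p2, p3])
        v1 = cm.compositions.loc["p1"].to_numpy()
        v2 = cm.compositions.loc["p2"].to_numpy()
        c1, c2 = v1 - v1.mean(), v2 - v2.mean()
        expected = (c1 @ c2) / np.sqrt((c1 @ c1) * (c2 @ c2))
        assert cm.correlations.loc["p1", "p2"] == pytest.approx(expected)


def _ortholog_with(families, pid="o"):
    """Protein with the given domain families at regular positions."""
    L = 60 * (len(families) + 1) + 40 * len(families)
    doms = []
    pos = 61
    for fam in families:
        doms.append((fam, pos, pos + 39))
        pos += 100
    return _protein(pid, "A" * L, domains=doms)


class TestAncestralComposition:
    def test_universal_domain_included(self):
        members = [_ortholog_with(["RRM"], f"o{i}") for i in range(5)]
        assert ar.ancestral_composition(members) == [("RRM", 1)]

    def test_exactly_30_percent_excluded(self):
        members = [_ortholog_with(["RRM"], f"o{i}") for i in range(3)]
        members += [_ortholog_with([], f"e{i}") for i in range(7)]
        assert ar.ancestral_composition(members) == []

    def test_partial_second_rrm(self):
        members = [_ortholog_with(["RRM", "RRM"], f"o{i}") for i in range(3)]
        members.append(_ortholog_with(["RRM"], "o3"))
        anc = ar.ancestral_composition(members)
        assert anc == [("RRM", 1), ("RRM", 2)]  # presence 1.0 and 0.75

    def test_empty_group_rejected(self):
        with pytest.raises(ContractError):
            ar.ancestral_composition([])


class TestConservedFraction:
    def test_identical_orthologs(self):
        members = [_ortholog_with(["RRM", "KH"], f"o{i}") for i in range(4)]
        frac, flags = ar.conserved_fraction(members)
        assert frac == 1.0 and all(flags)

    def test_three_of_four(self):
        members = [_ortholog_with(["RRM", "KH"], f"o{i}") for i in range(3)]
        members.append(_ortholog_with(["RRM"], "o3"))
        anc = ar.ancestral_composition(members)
        frac, _ = ar.conserved_fraction(members, anc)
        assert frac == pytest.approx(0.75)

    def test_swapped_order_not_conserved(self):
        members = [_ortholog_with(["RRM", "KH"], f"o{i}") for i in range(3)]
        swapped = _ortholog_with(["KH", "RRM"], "sw")
        anc = ar.ancestral_composition(members + [swapped])
        assert anc == [("RRM", 1), ("KH", 1)]
        assert not ar.has_conserved_organization(swapped, anc)

    def test_decreases_with_loss_probability(self):
        tpl = syn.make_template_protein(n_domains=2, families=("RRM", "KH"))
        fracs = []
        for p_loss in (0.0, 0.2, 0.5):
            vals = []
            for seed in range(5):
                g = syn.simulate_ortholog_group(
                    tpl, 20, 0.02, 0.01, p_loss, seed=seed
                )
                frac, _ = ar.conserved_fraction(
                    g.members, ar.ancestral_composition(g.members)
                )
                vals.append(frac)
            fracs.append(np.mean(vals))
        assert fracs[0] > fracs[1] > fracs[2]


class TestIdrSegmentConservation:
    def _two_orthologs_with_counts(self, c1, c2):
        """One inter-domain segment whose disordered-residue counts are c1, c2."""
        members = []
        for pid, c in (("o1", c1), ("o2", c2)):
            seg = max(c1, c2)
            L = 20 + seg + 20
            dis = np.zeros(L)
            dis[20 : 20 + c] = 0.95  # disordered residues in the linker
            dis[20 + c : 20 + seg] = 0.30  # ordered filler keeps counts at c
            doms = [("RRM", 1, 20), ("KH", L - 19, L)]
            members.append(_protein(pid, "A" * L, domains=doms, disorder=dis))
        return members

    def test_hand_computed_ratio(self):
        members = self._two_orthologs_with_counts(20, 40)
        anc = ar.ancestral_composition(members)
        segs, mean_ratio = ar.idr_segment_conservation(
            members, anc, [True, True]
        )
        assert len(segs) == 1
        s = segs[0]
        assert s.mean_count == pytest.approx(30.0)
        assert s.std_count == pytest.approx(14.142, abs=1e-3)
        assert s.ratio == pytest.approx(0.4714, abs=1e-4)
        assert mean_ratio == pytest.approx(s.ratio)

    def test_identical_orthologs_zero_ratio(self):
        tpl = syn.make_template_protein(n_domains=2, families=("RRM", "KH"))
        g = syn.simulate_ortholog_group(tpl, 5, 0.0, 0.0, 0.0, seed=1)
        grp = ar.analyze_ortholog_group(g.members)
        assert grp.mean_ratio == pytest.approx(0.0)
        assert all(s.ratio == 0.0 for s in grp.idr_segments)

    def test_low_disorder_segment_excluded(self):
        members = []
        for pid in ("o1", "o2"):
            L = 80
            dis = np.full(L, 0.4)  # average disorder below cutoff
            doms = [("RRM", 1, 20), ("KH", 61, 80)]
            members.append(_protein(pid, "A" * L, domains=doms, disorder=dis))
        anc = ar.ancestral_composition(members)
        segs, mean_ratio = ar.idr_segment_conservation(members, anc, [True, True])
        assert segs == [] and mean_ratio is None

    def test_ratio_scale_invariant(self):
        small = self._two_orthologs_with_counts(10, 20)
        large = self._two_orthologs_with_counts(30, 60)
        r_small = ar.idr_segment_conservation(
            small, ar.ancestral_composition(small), [True, True]
        )[1]
        r_large = ar.idr_segment_conservation(
            large, ar.ancestral_composition(large), [True, True]
        )[1]
        assert r_small == pytest.approx(r_large)


class TestInputTables:
    def test_load_architectures_roundtrip(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        fasta.write_text(">p1\nACDEFGHIKL\n")
        (tmp_path / "dom.tsv").write_text(
            "protein_id\tfamily\tstart\tend\np1\tRRM\t2\t5\n"
        )
        rows = ["protein_id\tposition\tscore"] + [
            f"p1\t{i}\t0.8" for i in range(1, 11)
        ]
        (tmp_path / "dis.tsv").write_text("\n".join(rows) + "\n")
        prots = ar.load_architectures(
            fasta, tmp_path / "dom.tsv", tmp_path / "dis.tsv"
        )
        p = prots["p1"]
        assert p.domains == [("RRM", 2, 5)]
        assert ar.region_fractions(p)[0] == pytest.approx(0.4)

    def test_synthetic_disorder_score_is_bounded(self):
        s = ar.synthetic_disorder_score("ACDEFGHIKLMNPQRSTVWY" * 3)
        assert (s >= 0).all() and (s <= 1).all()
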