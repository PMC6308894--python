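"""Consensus primer design, coverage gain and universal-tail vetting."""

import numpy as np
import pytest

from ambiprime.coverage import mismatch_profile
from ambiprime.design import (
    ColumnProfile,
    check_tail,
    column_profiles,
    coverage_gain,
    propose_degenerate_primer,
)
from ambiprime.iupac import expand, revcomp
from ambiprime.primers import get_primer
from ambiprime.reference import ReferenceSet, SequenceRecord

TAIL1_FWD = "cacctgcttctaaat"  # forward universal tail of the built-in panel


class TestColumnProfiles:
    def test_monomorphic_column(self):
        profs = column_profiles(["A" * 6] * 10)
        assert profs[0].freq == {"A": 1.0}
        assert profs[0].n == 10

    def test_even_split(self):
        profs = column_profiles(["AAAAAA"] * 5 + ["GAAAAA"] * 5)
        assert profs[0].freq == {"A": 0.5, "G": 0.5}

    def test_ambiguous_template_excluded_but_tallied(self):
        profs = column_profiles(["AAAAAA"] * 9 + ["NAAAAA"])
        assert profs[0].freq == {"A": 1.0}
        assert profs[0].n == 9
        assert profs[0].n_ambiguous == 1

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="covering"):
            column_profiles([])


class TestProposePrimer:
    def _prof(self, freqs):
        return [
            ColumnProfile(column=i, freq=f, n=100) for i, f in enumerate(freqs)
        ]

    def test_rare_base_excluded_common_kept(self):
        res = propose_degenerate_primer(
            self._prof([{"A": 0.99, "G": 0.01}] * 5), f_min=0.05
        )
        assert res.primer.sequence == "AAAAA"

    def test_even_column_becomes_purine_code(self):
        res = propose_degenerate_primer(self._prof([{"A": 0.5, "G": 0.5}] * 5))
        assert res.primer.sequence == "RRRRR"

    def test_all_bases_frequent_becomes_n(self):
        f = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
        res = propose_degenerate_primer(self._prof([f] * 5))
        assert res.primer.sequence == "NNNNN"

    def test_no_base_reaching_threshold_errors(self):
        profs = self._prof([{"A": 1.0}] * 4 + [{"A": 0.02, "C": 0.02, "G": 0.02, "T": 0.02}])
        with pytest.raises(ValueError, match="column 4"):
            propose_degenerate_primer(profs, f_min=0.05)

    def test_degeneracy_cap_prunes_lowest_entropy_first(self):
        # column 0 is nearly fixed (lowest entropy), column 1 is even
        profs = self._prof(
            [{"A": 0.94, "G": 0.06}, {"A": 0.5, "C": 0.5}, {"A": 1.0}, {"A": 1.0}, {"A": 1.0}]
        )
        res = propose_degenerate_primer(profs, f_min=0.05, max_degeneracy=2)
        # degeneracy 4 -> prune the near-fixed column's minor base first
        assert res.primer.sequence == "AMAAA"
        assert "column 0" in res.adjustments[0]

    def test_vanishing_threshold_gives_full_coverage(self):
        """At f_min -> 0+ the proposed primer matches every input exactly."""
        rng = np.random.default_rng(2)
        sites = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(30)]
        profs = column_profiles(sites)
        res = propose_degenerate_primer(profs, f_min=1e-9, max_degeneracy=4**8)
        for s in sites:
            prof = mismatch_profile(res.primer, s)
            assert (prof.m3, prof.m5) == (0, 0)

    def test_lower_threshold_monotone_in_coverage_and_degeneracy(self):
        rng = np.random.default_rng(3)
        sites = ["".join(rng.choice(list("ACGT"), p=[0.6, 0.2, 0.15, 0.05], size=10))
                 for _ in range(50)]
        profs = column_profiles(sites)
        prev_cov, prev_deg = -1.0, 0
        for f_min in (0.5, 0.3, 0.1, 0.04, 0.01):
            res = propose_degenerate_primer(profs, f_min=f_min, max_degeneracy=4**10)
            deg = res.primer.degeneracy
            cov = np.mean(
                [
                    (lambda p: p.m3 == 0 and p.m5 == 0)(mismatch_profile(res.primer, s))
                    for s in sites
                ]
            )
            assert deg >= prev_deg
            assert cov >= prev_cov - 1e-12
            prev_cov, prev_deg = cov, deg


class TestCoverageGain:
    def test_identical_primers_zero_gain(self):
        p = get_primer("Sauron-S878")
        sites = sorted(expand(p.sequence))[:20]
        rep = coverage_gain(p, p, sites)
        assert (rep.by_group["gain"] == 0).all()
        assert (rep.by_position["n_rescued"] == 0).all()

    def test_third_base_from_3prime_rescued_by_added_degeneracy(self):
        """A template with G where the narrower primer has Y (3rd base from
        the 3' end) mismatches it but matches the broader primer's N."""
        old = get_primer("mlCOIintF")
        new = get_primer("Sauron-S878")
        site = list(sorted(expand(old.sequence))[0])
        pos = len(site) - 3  # 3rd base from the 3' end
        assert old.sequence[pos] == "Y" and new.sequence[pos] == "N"
        site[pos] = "G"
        site = "".join(site)
        p_old = mismatch_profile(old, site)
        p_new = mismatch_profile(new, site)
        assert (p_old.m3, p_old.m5) == (1, 0)
        assert (p_new.m3, p_new.m5) == (0, 0)

    def test_planted_class_variant_yields_expected_gain(self):
        old = get_primer("mlCOIintF")
        new = get_primer("Sauron-S878")
        base = sorted(expand(old.sequence))[0]
        variant = list(base)
        variant[len(base) - 3] = "G"
        variant = "".join(variant)
        # class A: 25% carry the 3'-zone variant; class B: all match
        sites = {f"a{i}": (variant if i < 5 else base) for i in range(20)}
        sites.update({f"b{i}": base for i in range(10)})
        tax = {k: ("ClassA" if k.startswith("a") else "ClassB") for k in sites}
        rep = coverage_gain(old, new, sites, criterion=(0, 3), taxonomy=tax)
        by = rep.by_group.set_index("group")
        assert by.loc["ClassA", "gain"] == pytest.approx(0.25)
        assert by.loc["ClassB", "gain"] == pytest.approx(0.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            coverage_gain(get_primer("Sauron-S878"), get_primer("mLepR1"), ["ACGT"])


def _random_refset(n=20, length=200, seed=9):
    rng = np.random.default_rng(seed)
    recs = [
        SequenceRecord(
            seq_id=f"r{i:02d}",
            sequence="".join(rng.choice(list("ACGT"), size=length)),
            species=f"sp {i}",
        )
        for i in range(n)
    ]
    return ReferenceSet(recs)


class TestCheckTail:
    def test_planted_tail_fails_with_identity_one(self):
        rs = _random_refset()
        seq = rs.records[3].sequence
        planted = seq[:50] + TAIL1_FWD.upper() + seq[50 + len(TAIL1_FWD):]
        recs = list(rs.records)
        recs[3] = SequenceRecord(seq_id="r03", sequence=planted, species="sp 3")
        chk = check_tail(TAIL1_FWD, ReferenceSet(recs))
        assert not chk.passed
        assert chk.max_identity == pytest.approx(1.0)
        assert chk.seq_id == "r03" and chk.offset == 50

    def test_tail_passes_on_random_references(self):
        """The panel's forward tail fits poorly on random sequence; frozen
        against an exhaustive python-loop identity scan."""
        rs = _random_refset()
        chk = check_tail(TAIL1_FWD, rs)
        # independent oracle: naive double loop over strands and offsets
        tail = TAIL1_FWD.upper()
        best = 0.0
        for rec in rs:
            for probe in (tail, revcomp(tail)):
                for off in range(len(rec.sequence) - len(tail) + 1):
                    window = rec.sequence[off : off + len(tail)]
                    ident = sum(a == b for a, b in zip(probe, window)) / len(tail)
                    best = max(best, ident)
        assert chk.max_identity == pytest.approx(best)
        assert chk.passed  # below the 0.85 default threshold

    def test_empty_reference_passes_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            chk = check_tail(TAIL1_FWD, ReferenceSet([]))
        assert chk.passed

    def test_short_tail_rejected(self):
        with pytest.raises(ValueError, match="short"):
            check_tail("ACGTAC", _random_refset())
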