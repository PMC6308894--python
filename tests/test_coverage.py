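"""Zoned mismatch profiles, the criteria grid, and primer comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ambiprime.coverage import (
    MismatchProfile,
    compare_primer_success,
    coverage_by_group,
    criteria_grid,
    evaluate_panel,
    mismatch_profile,
)
from ambiprime.iupac import expand, revcomp
from ambiprime.primers import DegeneratePrimer, get_primer
from ambiprime.reference import ReferenceSet, SequenceRecord


def brute_force_zoned(primer, site_seq, zone=4):
    """Independent oracle: minimum zoned mismatches over all literal
    expansions of the primer, compared character-by-character."""
    template = site_seq if primer.orientation == "forward" else revcomp(site_seq)
    best3 = best5 = len(site_seq) + 1
    for exp in expand(primer.locus_sequence):
        mism = [a != b for a, b in zip(exp, template)]
        m3, m5 = sum(mism[-zone:]), sum(mism[:-zone])
        best3, best5 = min(best3, m3), min(best5, m5)
    return best3, best5


class TestMismatchProfile:
    def test_perfect_match_is_zero_zero(self):
        p = get_primer("Sauron-S878")
        site = sorted(expand(p.sequence))[0]
        prof = mismatch_profile(p, site)
        assert (prof.m3, prof.m5) == (0, 0)

    def test_three_prime_terminal_substitution(self):
        p = DegeneratePrimer(name="p", sequence="ACGTACGTAC")
        site = "ACGTACGTAG"  # last base C->G
        prof = mismatch_profile(p, site)
        assert (prof.m3, prof.m5) == (1, 0)

    def test_five_prime_most_substitution(self):
        p = DegeneratePrimer(name="p", sequence="ACGTACGTAC")
        site = "TCGTACGTAC"
        prof = mismatch_profile(p, site)
        assert (prof.m3, prof.m5) == (0, 1)

    def test_reverse_primer_three_prime_zone_substitution(self):
        """A substitution placed in the primer's 3' zone of a reverse-primer
        site profiles as (1, 0); frozen against the expansion oracle."""
        p = get_primer("jgHCO2198")
        exp = sorted(expand(p.sequence))[0]
        site = list(revcomp(exp))  # plus-strand footprint
        # primer position L-1 (3' terminal, a plain 'A') maps to site column 0
        assert p.sequence[-1] == "A"
        site[0] = "G"  # complement G != A -> guaranteed 3'-zone mismatch
        site = "".join(site)
        prof = mismatch_profile(p, site)
        assert (prof.m3, prof.m5) == (1, 0)
        assert brute_force_zoned(p, site) == (1, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mismatch_profile(get_primer("Sauron-S878"), "ACGT")

    @pytest.mark.parametrize("name", ["Sauron-S878", "mlCOIintF", "jgHCO2198"])
    def test_oracle_equivalence_on_random_sites(self, name):
        """Set-logic profiling equals the brute-force expansion minimum."""
        p = get_primer(name)
        rng = np.random.default_rng(17)
        L = len(p.locus_sequence)
        for _ in range(50):
            site = "".join(rng.choice(list("ACGT"), size=L))
            prof = mismatch_profile(p, site)
            assert (prof.m3, prof.m5) == brute_force_zoned(p, site)


def _refset_with_profiles(primer, site_specs):
    """Build a tiny aligned refset: each entry is (seq_id, class, site_str)
    with the site at columns 10..10+L; one record is truncated (gaps)."""
    L = len(primer.locus_sequence)
    records = []
    for seq_id, class_, site in site_specs:
        if site is None:  # does not span the site
            aligned = "-" * (10 + L) + "TTGGTTGGTT"
        else:
            aligned = "TTGGTTGGTT" + site + "GGGGGGGGGG"
        records.append(
            SequenceRecord(
                seq_id=seq_id,
                sequence=aligned.replace("-", ""),
                species=f"sp {seq_id}",
                class_=class_,
                aligned=aligned,
            )
        )
    return ReferenceSet(records)


class TestEvaluatePanel:
    def test_planted_profiles_and_exclusions(self):
        p = DegeneratePrimer(name="p", sequence="ACGTWCGTAC")
        perfect = "ACGTACGTAC"
        bad3 = "ACGTACGTAG"  # 3'-terminal mismatch
        specs = [(f"s{i}", "A", perfect) for i in range(9)]
        specs += [("s9", "A", bad3), ("s10", "A", None)]
        rs = _refset_with_profiles(p, specs)
        ev = evaluate_panel(rs, [p])
        covered = [x for x in ev.profiles if x.covered]
        assert len(covered) == 10
        counts = {(x.m3, x.m5) for x in covered}
        assert counts == {(0, 0), (1, 0)}
        assert sum(1 for x in covered if (x.m3, x.m5) == (1, 0)) == 1
        not_cov = [x for x in ev.profiles if not x.covered]
        assert len(not_cov) == 1 and not_cov[0].reason == "terminal_gap"


class TestCriteriaGrid:
    def _profiles(self, pairs):
        return [
            MismatchProfile(seq_id=f"s{i}", primer_name="p", covered=True, m3=a, m5=b)
            for i, (a, b) in enumerate(pairs)
        ]

    def test_all_perfect_gives_all_ones(self):
        g = criteria_grid(self._profiles([(0, 0)] * 5))
        assert len(g) == 20
        assert (g["proportion"] == 1.0).all()

    def test_single_3prime_mismatch_partitions_cells(self):
        g = criteria_grid(self._profiles([(0, 0)] * 9 + [(1, 0)]))
        strict = g[g.max_m3 == 0]
        relaxed = g[g.max_m3 >= 1]
        assert (strict["proportion"] == 0.9).all()
        assert (relaxed["proportion"] == 1.0).all()

    def test_zero_covering_is_undefined_not_zero(self):
        profiles = [
            MismatchProfile(seq_id="s", primer_name="p", covered=False, reason="terminal_gap")
        ]
        g = criteria_grid(profiles)
        assert g["proportion"].isna().all()
        assert (g["n_covering"] == 0).all()

    def test_grid_monotone_along_both_axes(self, demo_fixture):
        primers = [get_primer(n) for n in demo_fixture.sites]
        ev = evaluate_panel(
            demo_fixture.refset, primers, sites=demo_fixture.sites
        )
        g = criteria_grid(ev)
        for (_, _), sub in g.groupby(["primer", "max_m5"]):
            assert sub.sort_values("max_m3")["proportion"].is_monotonic_increasing
        for (_, _), sub in g.groupby(["primer", "max_m3"]):
            assert sub.sort_values("max_m5")["proportion"].is_monotonic_increasing

    def test_subset_mode_never_exceeds_intersection(self):
        """With ambiguous template characters, subset mode is conservative."""
        p = DegeneratePrimer(name="p", sequence="ACGTWCGTAC")
        sites = ["ACGTNCGTAC", "ACNTACGTAC", "ACGTACGTNN", "ACGTACGTAC"]
        for mode_pair in [("subset", "intersection")]:
            profs = {
                m: [mismatch_profile(p, s, seq_id=str(i), mode=m) for i, s in enumerate(sites)]
                for m in mode_pair
            }
            g_sub = criteria_grid(profs["subset"], mode="subset")
            g_int = criteria_grid(profs["intersection"], mode="intersection")
            assert (g_sub["proportion"] <= g_int["proportion"] + 1e-12).all()


class TestCoverageByGroup:
    def test_weighted_group_means_reconstruct_overall(self):
        profiles = [
            MismatchProfile(f"a{i}", "p", True, m3=0, m5=0) for i in range(9)
        ] + [
            MismatchProfile("a9", "p", True, m3=1, m5=0)
        ] + [
            MismatchProfile(f"b{i}", "p", True, m3=0, m5=0) for i in range(5)
        ]
        tax = {f"a{i}": "ClassA" for i in range(10)}
        tax.update({f"b{i}": "ClassB" for i in range(5)})
        t = coverage_by_group(profiles, tax, max_m3=0, max_m5=3)
        by = t.set_index("group")
        assert by.loc["ClassA", "proportion"] == pytest.approx(0.9)
        assert by.loc["ClassB", "proportion"] == pytest.approx(1.0)
        assert by.loc["OVERALL", "proportion"] == pytest.approx(14 / 15)
        classes = t[t.group != "OVERALL"]
        weighted = (classes.proportion * classes.n_covering).sum() / classes.n_covering.sum()
        assert weighted == pytest.approx(by.loc["OVERALL", "proportion"])

    def test_absent_class_gets_no_row(self):
        profiles = [MismatchProfile("a0", "p", True, m3=0, m5=0)]
        t = coverage_by_group(profiles, {"a0": "ClassA", "zz": "ClassC"}, 0, 3)
        assert set(t.group) == {"ClassA", "OVERALL"}


class TestComparePrimerSuccess:
    def test_identical_outcomes_give_null_contrast(self):
        v = [True] * 8 + [False] * 2
        rep = compare_primer_success({"p1": v, "p2": list(v)})
        row = rep.contrasts.iloc[0]
        assert abs(row.estimate) < 1e-6
        assert row.p_wald > 0.9

    def test_large_difference_detected_and_matches_fisher(self):
        rng = np.random.default_rng(0)
        a = [True] * 98 + [False] * 2
        b = [True] * 50 + [False] * 50
        rep = compare_primer_success({"good": a, "bad": b}, reference="bad")
        row = rep.contrasts.iloc[0]
        assert row.estimate > 0
        assert row.p_wald < 1e-3
        # independent oracle: Fisher exact on the 2x2 table
        oracle = stats.fisher_exact([[98, 2], [50, 50]])[1]
        assert row.p_exact == pytest.approx(oracle)
        assert not rep.separation

    def test_complete_separation_flagged_with_fallback(self):
        rep = compare_primer_success(
            {"all_win": [True] * 30, "mixed": [True] * 15 + [False] * 15}
        )
        assert rep.separation
        assert np.isfinite(rep.contrasts["p_exact"]).all()

    def test_all_identical_everywhere_reports_zero_no_crash(self):
        rep = compare_primer_success({"p1": [True] * 5, "p2": [True] * 5})
        assert (rep.contrasts["estimate"].abs() < 1e-9).all()

    def test_requires_two_primers_with_outcomes(self):
        with pytest.raises(ValueError):
            compare_primer_success({"only": [True]})
        with pytest.raises(ValueError):
            compare_primer_success({"a": [True], "b": []})
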