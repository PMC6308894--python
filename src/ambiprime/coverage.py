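"""Zoned-mismatch coverage evaluation of degenerate primers.

The central statistic: for each primer and each site-covering reference
sequence, mismatches are counted separately in the four bases closest to
the primer's 3′ end — where even a single mismatch can abolish polymerase
extension — and in the remaining 5′ bases, which tolerate more.  Crossing
the two maxima (0–3 mismatches in the 3′ zone × 0–4 in the remainder)
yields a 4×5 grid of nested acceptance criteria; the fraction of covering
sequences satisfying each cell, overall and per taxonomic class, is the
primer's *coverage* under that criterion.

Each primer is evaluated independently against its own site so a record
need not span both priming sites of a pair to contribute.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iupac import revcomp, symbols_match
from .primers import THREE_PRIME_ZONE, DegeneratePrimer
from .reference import ReferenceSet, SiteSpec, extract_site, locate_site

__all__ = [
    "MismatchProfile",
    "PanelEvaluation",
    "mismatch_profile",
    "evaluate_panel",
    "criteria_grid",
    "coverage_by_group",
    "compare_primer_success",
    "PrimerComparison",
]

#: Remainder-zone maxima evaluated in the criteria grid.
M5_LEVELS = range(5)


@dataclass(frozen=True)
class MismatchProfile:
    """Zoned mismatch counts of one primer against one site sequence.

    ``m3`` counts mismatches within the 3′ terminal zone (last *zone* bases
    of the primer as written 5′→3′), ``m5`` within the remaining bases.
    Both are None when the record does not cover the site.
    """

    seq_id: str
    primer_name: str
    covered: bool
    m3: int | None = None
    m5: int | None = None
    reason: str | None = None


def mismatch_profile(
    primer: DegeneratePrimer,
    site_seq: str,
    *,
    seq_id: str = "",
    mode: str = "intersection",
    zone: int = THREE_PRIME_ZONE,
) -> MismatchProfile:
    """Count zoned mismatches of *primer* against a plus-strand site string.

    The caller passes the site in template plus-strand orientation; reverse
    primers are compared against its reverse complement so the comparison
    always runs 5′→3′ along the primer.  A position mismatches when
    :func:`~ambiprime.iupac.symbols_match` is false under *mode*.
    """
    pseq = primer.locus_sequence
    if len(site_seq) != len(pseq):
        raise ValueError(
            f"site length {len(site_seq)} != primer length {len(pseq)} "
            f"for primer {primer.name!r}"
        )
    template = site_seq if primer.orientation == "forward" else revcomp(site_seq)
    mism = [
        not symbols_match(p, t, mode) for p, t in zip(pseq, template)
    ]
    m3 = sum(mism[-zone:])
    m5 = sum(mism[:-zone])
    return MismatchProfile(
        seq_id=seq_id, primer_name=primer.name, covered=True, m3=m3, m5=m5
    )


@dataclass
class PanelEvaluation:
    """Profiles for a panel of primers over one reference alignment."""

    profiles: list[MismatchProfile]
    sites: dict[str, SiteSpec]
    mode: str
    zone: int = THREE_PRIME_ZONE

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seq_id": [p.seq_id for p in self.profiles],
                "primer": [p.primer_name for p in self.profiles],
                "covered": [p.covered for p in self.profiles],
                "m3": [p.m3 for p in self.profiles],
                "m5": [p.m5 for p in self.profiles],
                "reason": [p.reason for p in self.profiles],
            }
        )


def evaluate_panel(
    refset: ReferenceSet,
    primers: list[DegeneratePrimer],
    *,
    mode: str = "intersection",
    zone: int = THREE_PRIME_ZONE,
    sites: dict[str, SiteSpec] | None = None,
    subsample: int | None = 1000,
    seed: int = 0,
) -> PanelEvaluation:
    """Locate each primer's site and profile every record against it.

    Each primer is treated independently: its site is located (unless
    provided via *sites*), every record's site string extracted, and
    covered records profiled.  Per-primer denominators therefore differ —
    a record may cover one primer's site but not another's.
    """
    located = dict(sites or {})
    profiles: list[MismatchProfile] = []
    for primer in primers:
        site = located.get(primer.name)
        if site is None:
            site = locate_site(refset, primer, subsample=subsample, seed=seed)
            located[primer.name] = site
        L = len(primer.locus_sequence)
        for rec in refset:
            ext = extract_site(rec, site, primer_length=L)
            if not ext.covered:
                profiles.append(
                    MismatchProfile(
                        seq_id=rec.seq_id,
                        primer_name=primer.name,
                        covered=False,
                        reason=ext.reason,
                    )
                )
            else:
                profiles.append(
                    mismatch_profile(
                        primer, ext.site_seq, seq_id=rec.seq_id, mode=mode, zone=zone
                    )
                )
    return PanelEvaluation(profiles=profiles, sites=located, mode=mode, zone=zone)


def _grid_rows(
    profiles: list[MismatchProfile],
    group: str,
    mode: str,
    zone: int,
) -> list[dict]:
    by_primer: dict[str, list[MismatchProfile]] = {}
    for p in profiles:
        by_primer.setdefault(p.primer_name, []).append(p)
    rows = []
    for primer_name, plist in by_primer.items():
        covered = [p for p in plist if p.covered]
        n_cov = len(covered)
        for max_m3, max_m5 in itertools.product(range(zone), M5_LEVELS):
            n_match = sum(1 for p in covered if p.m3 <= max_m3 and p.m5 <= max_m5)
            rows.append(
                {
                    "primer": primer_name,
                    "max_m3": max_m3,
                    "max_m5": max_m5,
                    "group": group,
                    "n_covering": n_cov,
                    "n_matching": n_match,
                    # undefined (not zero) when nothing covers the site
                    "proportion": n_match / n_cov if n_cov else np.nan,
                    "mode": mode,
                }
            )
    return rows


def criteria_grid(
    evaluation: PanelEvaluation | list[MismatchProfile],
    *,
    mode: str = "intersection",
    zone: int = THREE_PRIME_ZONE,
) -> pd.DataFrame:
    """All (max 3′, max remainder) criterion cells, overall coverage.

    Returns a tidy frame with one row per primer × ``max_m3`` × ``max_m5``
    (4 × 5 = 20 cells per primer at the default zone width) and columns
    ``n_covering``, ``n_matching``, ``proportion``.  A zero denominator
    yields an undefined (NaN) proportion, never 0.
    """
    if isinstance(evaluation, PanelEvaluation):
        profiles, mode, zone = evaluation.profiles, evaluation.mode, evaluation.zone
    else:
        profiles = evaluation
    if not profiles:
        raise ValueError("criteria_grid requires at least one profile")
    return pd.DataFrame(_grid_rows(profiles, "OVERALL", mode, zone))


def coverage_by_group(
    evaluation: PanelEvaluation | list[MismatchProfile],
    taxonomy: pd.DataFrame | dict[str, str],
    max_m3: int = 0,
    max_m5: int = 3,
    *,
    mode: str = "intersection",
    zone: int = THREE_PRIME_ZONE,
) -> pd.DataFrame:
    """Coverage at one criterion, per taxonomic class plus OVERALL.

    *taxonomy* maps ``seq_id`` to class label (a dict, or a frame with
    ``seq_id``/``class`` columns).  One row per class present among
    covering sequences; classes absent from the covering set get no row.
    The OVERALL proportion equals the ``n_covering``-weighted mean of the
    class proportions.
    """
    if isinstance(evaluation, PanelEvaluation):
        profiles, mode, zone = evaluation.profiles, evaluation.mode, evaluation.zone
    else:
        profiles = evaluation
    if isinstance(taxonomy, pd.DataFrame):
        tax = dict(zip(taxonomy["seq_id"], taxonomy["class"]))
    else:
        tax = dict(taxonomy)

    rows: list[dict] = []
    by_primer: dict[str, list[MismatchProfile]] = {}
    for p in profiles:
        by_primer.setdefault(p.primer_name, []).append(p)
    for primer_name, plist in by_primer.items():
        covered = [p for p in plist if p.covered]
        groups: dict[str, list[MismatchProfile]] = {}
        for p in covered:
            groups.setdefault(tax.get(p.seq_id, ""), []).append(p)
        for group in sorted(groups):
            glist = groups[group]
            n_match = sum(1 for p in glist if p.m3 <= max_m3 and p.m5 <= max_m5)
            rows.append(
                {
                    "primer": primer_name,
                    "max_m3": max_m3,
                    "max_m5": max_m5,
                    "group": group,
                    "n_covering": len(glist),
                    "n_matching": n_match,
                    "proportion": n_match / len(glist) if glist else np.nan,
                    "mode": mode,
                }
            )
        n_cov = len(covered)
        n_match = sum(1 for p in covered if p.m3 <= max_m3 and p.m5 <= max_m5)
        rows.append(
            {
                "primer": primer_name,
                "max_m3": max_m3,
                "max_m5": max_m5,
                "group": "OVERALL",
                "n_covering": n_cov,
                "n_matching": n_match,
                "proportion": n_match / n_cov if n_cov else np.nan,
                "mode": mode,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PrimerComparison:
    """Binomial-GLM comparison of per-primer success proportions."""

    proportions: pd.DataFrame  # primer, n, n_success, proportion
    contrasts: pd.DataFrame  # primer, estimate, se, p_wald, p_holm, p_exact
    reference: str
    separation: bool
    note: str = ""


def compare_primer_success(
    outcomes: dict[str, list[bool]],
    reference: str | None = None,
) -> PrimerComparison:
    """Compare per-sequence success rates between primers.

    Fits a logistic model of success on primer identity and reports, for
    each non-reference primer, the log-odds contrast against *reference*
    (default: first primer by input order) with Wald p-values, Holm
    adjustment across contrasts, and a Fisher exact p-value per contrast.
    Complete separation (a primer with all-identical outcomes) is detected
    and flagged; the exact p-values then serve as the fallback.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two primers to compare")
    names = list(outcomes)
    if reference is None:
        reference = names[0]
    if reference not in outcomes:
        raise ValueError(f"reference primer {reference!r} not among outcomes")
    for name, v in outcomes.items():
        if len(v) == 0:
            raise ValueError(f"primer {name!r} has no outcomes")

    prop = pd.DataFrame(
        {
            "primer": names,
            "n": [len(outcomes[n]) for n in names],
            "n_success": [int(np.sum(outcomes[n])) for n in names],
        }
    )
    prop["proportion"] = prop["n_success"] / prop["n"]

    ordered = [reference] + [n for n in names if n != reference]
    y = np.concatenate([np.asarray(outcomes[n], dtype=float) for n in ordered])
    X = np.zeros((len(y), len(ordered)))
    X[:, 0] = 1.0
    pos = 0
    for j, n in enumerate(ordered):
        k = len(outcomes[n])
        if j > 0:
            X[pos : pos + k, j] = 1.0
        pos += k

    all_identical = len(set(y)) == 1
    # a primer whose outcomes are all-identical separates the logistic fit
    separation = (not all_identical) and any(
        len({bool(v) for v in outcomes[n]}) == 1 for n in names
    )

    est = np.zeros(len(ordered) - 1)
    se = np.full(len(ordered) - 1, np.nan)
    p_wald = np.ones(len(ordered) - 1)
    note = ""
    if all_identical:
        note = "all outcomes identical; contrasts are zero by construction"
    else:
        with np.errstate(all="ignore"):
            model = sm.GLM(y, X, family=sm.families.Binomial())
            try:
                res = model.fit(maxiter=200)
                est = res.params[1:]
                se = res.bse[1:]
                p_wald = res.pvalues[1:]
            except Exception:  # pragma: no cover - degenerate fits
                separation = True
                note = "GLM failed to converge; exact p-values are authoritative"

    ref_s = int(np.sum(outcomes[reference]))
    ref_n = len(outcomes[reference])
    p_exact = []
    for n in ordered[1:]:
        s = int(np.sum(outcomes[n]))
        table = [[s, len(outcomes[n]) - s], [ref_s, ref_n - ref_s]]
        p_exact.append(stats.fisher_exact(table)[1])

    p_holm = (
        multipletests(p_wald, method="holm")[1]
        if len(p_wald) > 1
        else np.asarray(p_wald)
    )
    contrasts = pd.DataFrame(
        {
            "primer": ordered[1:],
            "estimate": est,
            "se": se,
            "p_wald": p_wald,
            "p_holm": p_holm,
            "p_exact": p_exact,
        }
    )
    if separation and not note:
        note = (
            "complete separation detected (a primer with all-identical "
            "outcomes); Wald statistics unreliable, use p_exact"
        )
    return PrimerComparison(
        proportions=prop,
        contrasts=contrasts,
        reference=reference,
        separation=separation,
        note=note,
    )
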