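"""Mock-community sequencing simulator and detection-probability model.

Models the structure of a metabarcoding validation experiment: pooled mock
communities of DNA extracts with known concentrations are PCR-amplified
with a degenerate primer pair and sequenced to a finite depth, and each
member is scored detected or not.  Whether a taxon is recovered depends on
(i) its template concentration relative to the other members of the pool
and (ii) the sequencing depth — rare templates are simply not sampled at
shallow depth — with primer mismatches further eroding amplification
efficiency in the competitive reaction.

The chain is: concentrations (optionally balanced by capping at 5 μg/μl
and pooling equal volumes) → per-member amplification efficiency from its
zoned primer-mismatch profile → deterministic competitive-PCR weights →
one multinomial draw of reads at the library's depth → presence/absence
detection → a binomial GLM of detection on log relative concentration and
log depth (with McFadden's pseudo-R²).

The efficiency model ``e = e_max · δ3^m3 · δ5^m5`` and the multinomial
sequencing abstraction are this package's own simplifications: a 3′-zone
mismatch is far more damaging per unit (δ3 < δ5), which is the qualitative
behaviour motivating zoned evaluation.  Only relative concentrations enter
the model; units are carried as configured.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CommunityMember",
    "LibrarySpec",
    "SequencingRun",
    "EfficiencyParams",
    "DetectionFit",
    "build_mock_design",
    "balance_concentrations",
    "mismatch_to_efficiency",
    "simulate_amplification",
    "sample_reads",
    "detect",
    "derive_seed",
    "sample_community",
    "simulate_experiment",
    "fit_detection_model",
]

#: Default dilution cap for the balanced pooling level, in the
#: concentration units of the input (μg/μl in the emulated design).
BALANCE_CAP = 5.0

_CLASS_POOL = (
    "Insecta",
    "Arachnida",
    "Mammalia",
    "Aves",
    "Actinopterygii",
    "Amphibia",
    "Gastropoda",
    "Malacostraca",
    "Chromadorea",
    "Clitellata",
)


@dataclass(frozen=True)
class CommunityMember:
    """One DNA extract in a mock community."""

    taxon_id: str
    class_: str = ""
    concentration: float = 1.0
    m3: int = 0
    m5: int = 0
    efficiency: float | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.taxon_id}: concentration must be nonnegative")
        if self.efficiency is not None and not 0 <= self.efficiency <= 1:
            raise ValueError(f"{self.taxon_id}: efficiency must be in [0, 1]")


@dataclass(frozen=True)
class LibrarySpec:
    """One simulated library: a set × balance level × replicate cell."""

    library_id: str
    set_index: int
    balance: str
    replicate: int


@dataclass(frozen=True)
class SequencingRun:
    """Read counts for one library at a given total depth."""

    library_id: str
    depth: int
    counts: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("read counts must be nonnegative")
        if sum(self.counts) != self.depth:
            raise ValueError("counts must sum to depth")


@dataclass(frozen=True)
class EfficiencyParams:
    """Parameters of the mismatch → per-cycle efficiency map."""

    e_max: float = 0.95
    delta3: float = 0.3
    delta5: float = 0.8

    def __post_init__(self) -> None:
        for name in ("e_max", "delta3", "delta5"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def build_mock_design(
    n_sets: int = 3,
    balance_levels: tuple[str, ...] = ("balanced", "unbalanced"),
    replicates: int = 3,
) -> list[LibrarySpec]:
    """Enumerate the full factorial library design, deterministically.

    The emulated experiment used three sets of DNA extracts × two balance
    levels × three replicates = 18 individually tagged libraries.
    """
    if n_sets < 1 or replicates < 1 or len(balance_levels) < 1:
        raise ValueError("all design factors must have at least one level")
    specs = []
    for s in range(1, n_sets + 1):
        for level in balance_levels:
            for r in range(1, replicates + 1):
                specs.append(
                    LibrarySpec(
                        library_id=f"set{s}-{level}-rep{r}",
                        set_index=s,
                        balance=level,
                        replicate=r,
                    )
                )
    return specs


def balance_concentrations(
    members: list[CommunityMember], cap: float = BALANCE_CAP
) -> list[CommunityMember]:
    """Dilute every extract above *cap* down to *cap* (equal-volume pooling).

    Extracts already below the cap are left unaltered — low concentrations
    cannot be measured precisely enough to adjust upward.  Order preserved.
    """
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    return [
        replace(m, concentration=min(m.concentration, cap)) for m in members
    ]


def mismatch_to_efficiency(
    m3: int, m5: int, params: EfficiencyParams = EfficiencyParams()
) -> float:
    """Per-cycle amplification efficiency of a mismatched template.

    ``e = e_max · δ3^m3 · δ5^m5``: strictly decreasing in both counts, and
    a 3′-zone mismatch costs at least as much as a remainder mismatch
    whenever δ3 ≤ δ5.
    """
    if m3 < 0 or m5 < 0:
        raise ValueError("mismatch counts must be nonnegative")
    return params.e_max * params.delta3**m3 * params.delta5**m5


def _efficiency(m: CommunityMember, params: EfficiencyParams) -> float:
    if m.efficiency is not None:
        return m.efficiency
    return mismatch_to_efficiency(m.m3, m.m5, params)


def simulate_amplification(
    members: list[CommunityMember],
    cycles: int = 35,
    params: EfficiencyParams = EfficiencyParams(),
) -> np.ndarray:
    """Post-PCR relative template proportions (deterministic).

    Competitive exponential amplification:
    ``w_i = concentration_i · (1 + e_i)^cycles``, normalized.  Members with
    an explicit ``efficiency`` use it; otherwise efficiency derives from
    their mismatch profile.  Stochasticity enters only at read sampling.
    """
    if cycles < 0:
        raise ValueError("cycles must be nonnegative")
    conc = np.array([m.concentration for m in members], dtype=float)
    eff = np.array([_efficiency(m, params) for m in members], dtype=float)
    # log-space to avoid overflow at high cycle counts
    logw = np.where(conc > 0, np.log(np.where(conc > 0, conc, 1.0)), -np.inf)
    logw = logw + cycles * np.log1p(eff)
    if np.all(np.isneginf(logw)):
        raise ValueError("all amplification weights are zero")
    logw -= np.max(logw[np.isfinite(logw)])
    w = np.exp(logw)
    return w / w.sum()


def derive_seed(library_id: str, root_seed: int) -> int:
    """Deterministic per-library seed below 2^31, from the root seed."""
    h = hashlib.sha256(f"{library_id}:{root_seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def sample_reads(
    proportions: np.ndarray, depth: int, seed: int, library_id: str = "lib"
) -> SequencingRun:
    """One multinomial draw of *depth* reads over member proportions."""
    p = np.asarray(proportions, dtype=float)
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()}")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, p / p.sum())
    return SequencingRun(
        library_id=library_id, depth=depth, counts=tuple(int(c) for c in counts), seed=seed
    )


def detect(run: SequencingRun, r_min: int = 1) -> np.ndarray:
    """Presence/absence call per member: detected iff count ≥ *r_min*."""
    if r_min < 1:
        raise ValueError("r_min must be at least 1")
    return np.array([c >= r_min for c in run.counts])


def sample_community(
    n_members: int,
    rng: np.random.Generator,
    *,
    set_index: int = 1,
    conc_median: float = 2.5,
    conc_sigma: float = 1.2,
    p_m3: float = 0.02,
    mean_m5: float = 1.0,
) -> list[CommunityMember]:
    """Draw one mock community of extracts with realistic heterogeneity.

    Concentrations are lognormal (median *conc_median*, log-sd
    *conc_sigma*), emulating uncurated DNA extracts spanning roughly two
    orders of magnitude.  A small fraction *p_m3* of members carries a
    single 3′-zone primer mismatch (the well-covered-primer regime) and
    remainder mismatches are Poisson with mean *mean_m5*.  Classes are
    assigned round-robin from a pool of animal classes so group-level
    summaries have structure.
    """
    members = []
    for i in range(n_members):
        conc = float(conc_median * np.exp(conc_sigma * rng.standard_normal()))
        m3 = int(rng.random() < p_m3)
        m5 = int(rng.poisson(mean_m5))
        members.append(
            CommunityMember(
                taxon_id=f"set{set_index}-taxon{i + 1:03d}",
                class_=_CLASS_POOL[i % len(_CLASS_POOL)],
                concentration=conc,
                m3=m3,
                m5=m5,
            )
        )
    return members


def simulate_experiment(
    n_libraries: int = 18,
    members_per_library: int = 85,
    *,
    cycles: int = 35,
    depth_range: tuple[int, int] = (10_000, 55_000),
    balance_levels: tuple[str, ...] = ("balanced", "unbalanced"),
    cap: float = BALANCE_CAP,
    r_min: int = 1,
    params: EfficiencyParams = EfficiencyParams(),
    seed: int = 0,
    **community_kwargs,
) -> pd.DataFrame:
    """Simulate many libraries end-to-end and return tidy observations.

    Each library draws a fresh community, applies its balance level
    (alternating across libraries), amplifies, samples reads at a depth
    drawn log-uniformly from *depth_range* (the span of quality-filtered
    read counts in the emulated runs), and calls detections.  One root
    seed governs everything; per-library seeds are derived by hashing.

    Returns one row per member per library with columns ``library_id``,
    ``taxon_id``, ``class``, ``concentration``, ``rel_conc`` (pre-PCR
    concentration relative to the pool total), ``proportion`` (post-PCR),
    ``count``, ``detected``, ``depth``, ``seed``.
    """
    rows = []
    lo, hi = depth_range
    master = np.random.default_rng(seed)
    for i in range(n_libraries):
        level = balance_levels[i % len(balance_levels)]
        library_id = f"lib{i + 1:04d}-{level}"
        lib_seed = derive_seed(library_id, seed)
        rng = np.random.default_rng(lib_seed)
        members = sample_community(
            members_per_library, rng, set_index=i + 1, **community_kwargs
        )
        if level == "balanced":
            members = balance_concentrations(members, cap)
        conc = np.array([m.concentration for m in members])
        rel = conc / conc.sum()
        props = simulate_amplification(members, cycles, params)
        depth = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        run = sample_reads(props, depth, derive_seed(library_id + ":reads", seed), library_id)
        det = detect(run, r_min)
        for m, rc, pr, c, d in zip(members, rel, props, run.counts, det):
            rows.append(
                {
                    "library_id": library_id,
                    "taxon_id": m.taxon_id,
                    "class": m.class_,
                    "concentration": m.concentration,
                    "rel_conc": rc,
                    "proportion": pr,
                    "count": c,
                    "detected": bool(d),
                    "depth": depth,
                    "seed": lib_seed,
                }
            )
    _ = master  # reserved for future library-level draws
    return pd.DataFrame(rows)


@dataclass
class DetectionFit:
    """A fitted binomial logit model of detection probability.

    Covariates are log relative concentration and log depth, centered at
    their sample means so main effects are interpretable at a typical
    observation even when the interaction term is included.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    mcfadden_r2: float
    n: int
    interaction: bool
    center: tuple[float, float]  # means of (log rel_conc, log depth)
    separation: bool = False
    note: str = ""

    def predict(self, rel_conc, depth) -> np.ndarray:
        """Detection probability at given relative concentration and depth."""
        x1 = np.log(np.asarray(rel_conc, dtype=float)) - self.center[0]
        x2 = np.log(np.asarray(depth, dtype=float)) - self.center[1]
        x1, x2 = np.broadcast_arrays(x1, x2)
        eta = self.params["intercept"] + self.params["log_rel_conc"] * x1
        eta = eta + self.params["log_depth"] * x2
        if self.interaction:
            eta = eta + self.params["log_rel_conc:log_depth"] * x1 * x2
        return 1.0 / (1.0 + np.exp(-eta))

    def prediction_grid(
        self, rel_conc_values, depth_values
    ) -> pd.DataFrame:
        """Predicted detection surface over a concentration × depth grid."""
        rows = []
        for d in depth_values:
            p = self.predict(np.asarray(rel_conc_values), d)
            for rc, pi in zip(rel_conc_values, p):
                rows.append({"rel_conc": rc, "depth": d, "p_detect": pi})
        return pd.DataFrame(rows)


def fit_detection_model(
    observations: pd.DataFrame,
    *,
    interaction: bool = True,
    center: bool = True,
) -> DetectionFit:
    """Fit detection ~ log relative concentration × log sequencing depth.

    *observations* needs columns ``detected`` (bool), ``rel_conc`` (> 0)
    and ``depth`` (> 0).  The binomial logit model is fit by IRLS via
    statsmodels; McFadden's pseudo-R² is ``1 − loglik/loglik_null``.
    Complete separation is flagged and a ridge-penalized fallback fit is
    used (and labeled) in that case.
    """
    obs = observations
    y = obs["detected"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both detected and undetected outcomes to fit")
    x1 = np.log(obs["rel_conc"].to_numpy(dtype=float))
    x2 = np.log(obs["depth"].to_numpy(dtype=float))
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("covariates must be finite and positive")
    c1, c2 = (float(x1.mean()), float(x2.mean())) if center else (0.0, 0.0)
    x1c, x2c = x1 - c1, x2 - c2

    names = ["intercept", "log_rel_conc", "log_depth"]
    cols = [np.ones_like(x1c), x1c, x2c]
    if interaction:
        names.append("log_rel_conc:log_depth")
        cols.append(x1c * x2c)
    X = np.column_stack(cols)

    separation = False
    note = ""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        with np.errstate(all="ignore"):
            res = model.fit(maxiter=200)
        params = res.params
        bse = res.bse
        pvalues = res.pvalues
        llf, llnull = res.llf, res.llnull
    except Exception:
        separation = True
        note = "complete separation: ridge-penalized fallback fit"
        res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
        params = res.params
        bse = np.full(len(params), np.nan)
        pvalues = np.full(len(params), np.nan)
        eta = X @ params
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        p0 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        llnull = float(len(y) * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))

    mcfadden = float(1.0 - llf / llnull) if llnull != 0 else 0.0
    return DetectionFit(
        params=pd.Series(params, index=names),
        bse=pd.Series(np.asarray(bse), index=names),
        pvalues=pd.Series(np.asarray(pvalues), index=names),
        mcfadden_r2=mcfadden,
        n=len(y),
        interaction=interaction,
        center=(c1, c2),
        separation=separation,
        note=note,
    )
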