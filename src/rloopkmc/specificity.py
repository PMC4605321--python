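"""Off-target specificity pipeline: mismatch annotation, dataset filtering,
per-pair KMC stability metrics, and permutation-tested correlation with
experimental cleavage frequencies.

The stability metric for a guide/target pair is the mean fraction of time
the R-loop extends to at least position m* (default 16) over replicate
invasions started at m0 = 10 with an absorbing boundary at m = 0, run to
max_t = 100 (arbitrary units) -- the conditions under which R-loop
stability was found to track off-target cleavage.  Association with
cleavage frequencies is measured by the Pearson correlation coefficient
with a two-sided permutation p-value (pairing permuted, +1 smoothing).
"""

from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import observables
from .invasion_kmc import ABSORBING, build_rate_table, simulate_residency
from .thermo import (
    CANONICAL_MISMATCHES,
    EnergyModel,
    GuideTargetPair,
    duplex_binding_energy,
    normalize_sequence,
)

logger = logging.getLogger(__name__)

#: PAM-distal cutoff used for the off-target dataset filter
PAM_DISTAL_CUTOFF = 10


@dataclass
class SpecificityRecord:
    """One guide/target pair with its cleavage frequency and derived metrics."""

    record_id: str
    pair: GuideTargetPair
    cutting_frequency: float
    mismatch_position: int | None = None
    mismatch_type: str | None = None
    stability: float = float("nan")
    stability_sem: float = float("nan")
    binding_energy: float = float("nan")


def annotate_mismatches(guide: str, target: str) -> list[tuple[int, str, bool]]:
    """Ordered (position, class, isolated) annotations for a guide/target pair.

    ``target`` is the PAM-proximal N bp of the protospacer written on the
    guide-matching strand (N = guide length); positions count from the PAM.
    ``isolated`` is False when an adjacent position is also mismatched.
    """
    guide = normalize_sequence(guide, "rna")
    target = normalize_sequence(target, "dna")
    if len(guide) != len(target):
        raise ValueError(
            f"guide ({len(guide)} nt) and target ({len(target)} bp) lengths differ"
        )
    pair = GuideTargetPair(guide=guide, protospacer=target)
    positions = {pos for pos, _ in pair.mismatches}
    return [
        (pos, cls, (pos - 1 not in positions) and (pos + 1 not in positions))
        for pos, cls in pair.mismatches
    ]


def filter_offtarget_set(
    records: list[SpecificityRecord],
    min_position: int = PAM_DISTAL_CUTOFF,
) -> tuple[list[SpecificityRecord], dict[str, int]]:
    """Keep records with exactly one PAM-distal mismatch of a canonical type.

    Retains records whose pair carries exactly one mismatch, at position
    >= ``min_position``, of type rG.dG / rC.dC / rA.dA / rU.dT; returns the
    surviving records (with mismatch fields filled) and per-reason
    rejection counts.
    """
    kept: list[SpecificityRecord] = []
    reasons = {"multiple_or_no_mismatch": 0, "pam_proximal": 0, "type_other": 0}
    for rec in records:
        mm = rec.pair.mismatches
        if len(mm) != 1:
            reasons["multiple_or_no_mismatch"] += 1
            continue
        pos, cls = mm[0]
        if pos < min_position:
            reasons["pam_proximal"] += 1
            continue
        if cls not in CANONICAL_MISMATCHES:
            reasons["type_other"] += 1
            continue
        rec.mismatch_position = pos
        rec.mismatch_type = cls
        kept.append(rec)
    logger.info(
        "filter_offtarget_set: kept %d of %d (%s)", len(kept), len(records), reasons
    )
    return kept, reasons


def record_seed(master_seed: int, record_id: str) -> int:
    """Deterministic per-record 31-bit seed from (master seed, record id).

    Stable under dataset growth: adding records never changes the seeds,
    and hence the metrics, of existing ones.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(record_id.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


def stability_metric(
    pair: GuideTargetPair,
    model: EnergyModel,
    m_star: int = 16,
    reps: int = 1000,
    m0: int = 10,
    max_t: float = 100.0,
    seed: int = 0,
    k0: float = 1.0,
    boundary: str = ABSORBING,
) -> observables.ThresholdOccupancy:
    """Mean fraction of time m >= m_star during invasion started at m0.

    Wraps rate construction, the replicate KMC ensemble, and the threshold
    occupancy reduction with the standard defaults (1000 replicates from
    m0 = 10 to max_t = 100, absorbing at 0, m* = 16); everything is
    overridable.
    """
    rates = build_rate_table(pair, model, k0=k0)
    ens = simulate_residency(rates, m0, max_t, reps, seed, boundary)
    return observables.threshold_occupancy(ens, m_star)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_perm: float
    n: int
    n_perm: int
    method: str
    exact: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    return float(xs @ ys / np.sqrt((xs @ xs) * (ys @ ys)))


def correlate_with_cleavage(
    metric: np.ndarray,
    frequency: np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
    method: str = "pearson",
    exact: bool | None = None,
) -> CorrelationResult:
    """Correlation between a stability metric and cleavage frequencies with a
    two-sided permutation p-value.

    The pairing between the two vectors is permuted ``n_perm`` times under a
    fixed seed; p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).  For tiny
    samples (n! <= n_perm, or ``exact=True``) every pairing is enumerated
    instead and p is the exact tail fraction over all n! permutations.
    ``method`` is ``"pearson"`` (default) or ``"spearman"`` (rank-transform
    first, then the same machinery).
    """
    x = np.asarray(metric, dtype=np.float64)
    y = np.asarray(frequency, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D vectors with n >= 3")
    if method == "spearman":
        from scipy.stats import rankdata

        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in metric or frequency vector")

    n = len(x)
    r_obs = _pearson(x, y)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    if exact is None:
        exact = math.factorial(n) <= n_perm
    tol = 1e-12
    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(xs @ ys[list(perm)]) / n
            count += abs(r) >= abs(r_obs) - tol
            total += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        chunk = max(1, min(n_perm, 20_000_000 // max(n, 1)))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            idx = np.argsort(rng.random((b, n)), axis=1)
            r = ys[idx] @ xs / n
            count += int((np.abs(r) >= abs(r_obs) - tol).sum())
            done += b
        p = (1 + count) / (1 + n_perm)
        n_used = n_perm
    return CorrelationResult(
        r=r_obs, p_perm=float(p), n=n, n_perm=n_used, method=method, exact=bool(exact)
    )


# ---------------------------------------------------------------------------
# dataset-level pipeline
# ---------------------------------------------------------------------------


def load_cleavage_table(path) -> list[SpecificityRecord]:
    """Read a guide/target cleavage TSV into specificity records.

    Expected columns: ``guide_id``, ``guide_seq``, ``target_seq``,
    ``cutting_frequency`` ('#'-comment lines allowed).  ``target_seq`` is
    the protospacer on the guide-matching strand (PAM excluded).  Suitable
    for externally assembled single-mismatch cleavage datasets.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"guide_id", "guide_seq", "target_seq", "cutting_frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cleavage table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        freq = float(row.cutting_frequency)
        if freq < 0:
            raise ValueError(f"negative cutting_frequency for {row.guide_id}")
        records.append(
            SpecificityRecord(
                record_id=str(row.guide_id),
                pair=GuideTargetPair(guide=row.guide_seq, protospacer=row.target_seq),
                cutting_frequency=freq,
            )
        )
    return records


@dataclass(frozen=True)
class PipelineResult:
    records: list[SpecificityRecord]
    correlation: CorrelationResult
    energy_correlation: CorrelationResult | None
    rejections: dict[str, int]
    settings: dict


def analyze_cleavage_dataset(
    records: list[SpecificityRecord],
    model: EnergyModel,
    master_seed: int = 0,
    m_star: int = 16,
    reps: int = 1000,
    m0: int = 10,
    max_t: float = 100.0,
    n_perm: int = 100_000,
    method: str = "pearson",
    min_position: int = PAM_DISTAL_CUTOFF,
    correlate_energy: bool = True,
) -> PipelineResult:
    """Full filter -> per-record KMC stability -> permutation correlation run.

    Per-record KMC seeds derive from (master_seed, record_id), so results
    are reproducible and insensitive to dataset ordering or growth.  Also
    computes each pair's hybridization free energy and (optionally) its
    correlation with cleavage, the baseline that R-loop stability is
    compared against.
    """
    kept, rejections = filter_offtarget_set(records, min_position=min_position)
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} records survive the filter; need >= 3")
    for rec in kept:
        occ = stability_metric(
            rec.pair,
            model,
            m_star=m_star,
            reps=reps,
            m0=m0,
            max_t=max_t,
            seed=record_seed(master_seed, rec.record_id),
        )
        rec.stability = occ.mean_frac
        rec.stability_sem = occ.sem
        rec.binding_energy = duplex_binding_energy(rec.pair, model)
    stab = np.array([r.stability for r in kept])
    freq = np.array([r.cutting_frequency for r in kept])
    corr = correlate_with_cleavage(
        stab, freq, n_perm=n_perm, seed=master_seed, method=method
    )
    e_corr = None
    if correlate_energy:
        energy = np.array([r.binding_energy for r in kept])
        if np.ptp(energy) > 0:
            e_corr = correlate_with_cleavage(
                energy, freq, n_perm=n_perm, seed=master_seed + 1, method=method
            )
    settings = dict(
        m_star=m_star,
        reps=reps,
        m0=m0,
        max_t=max_t,
        n_perm=n_perm,
        method=method,
        min_position=min_position,
        master_seed=master_seed,
    )
    return PipelineResult(
        records=kept,
        correlation=corr,
        energy_correlation=e_corr,
        rejections=rejections,
        settings=settings,
    )


def records_frame(result: PipelineResult) -> pd.DataFrame:
    """Record-level metrics as a DataFrame (for TSV output)."""
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in result.records],
            "guide_seq": [r.pair.guide for r in result.records],
            "target_seq": [r.pair.protospacer for r in result.records],
            "mismatch_position": [r.mismatch_position for r in result.records],
            "mismatch_type": [r.mismatch_type for r in result.records],
            "cutting_frequency": [r.cutting_frequency for r in result.records],
            "stability": [r.stability for r in result.records],
            "stability_sem": [r.stability_sem for r in result.records],
            "binding_energy": [r.binding_energy for r in result.records],
        }
    )
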