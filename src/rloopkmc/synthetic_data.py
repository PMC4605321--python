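"""Synthetic-data generators with known ground truth.

Three generators stand in for the pipeline's experimental inputs:

* random guide/protospacer pairs (perfect complements with a legal NGG PAM)
  into which a single canonical mismatch can be injected;
* cleavage-frequency datasets in which the cutting frequency is a noisy
  monotone (logistic) function of the pair's *true* simulated R-loop
  stability -- so the stability/cleavage correlation the pipeline should
  recover is built in and controllable (a zero slope gives a true null);
* protein-binding-event tables emulating single-molecule footprint data:
  per-site occupancy drawn from the single-site binding isotherm at a known
  Ka, footprint centers Gaussian-broadened (sigma defaults inside the
  36-60 bp range typical of such measurements), plus uniform background.

Ground truth is returned (and written) separately from the observed tables
so tests cannot accidentally feed truth into the pipeline.  Every output is
reproducible bit-for-bit from (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .specificity import SpecificityRecord, stability_metric
from .thermo import (
    DNA_COMPLEMENT,
    EnergyModel,
    GuideTargetPair,
    load_energy_model,
)

#: guide base -> the canonical mismatch class created by mutating the bound
#: strand to the same letter (rG.dG, rC.dC, rA.dA, rU.dT)
_TYPE_FOR_GUIDE_BASE = {"G": "rG.dG", "C": "rC.dC", "A": "rA.dA", "U": "rU.dT"}
#: canonical class -> (required guide base, bound-strand base after injection)
_INJECTION = {"rG.dG": ("G", "G"), "rC.dC": ("C", "C"), "rA.dA": ("A", "A"), "rU.dT": ("U", "T")}


@dataclass(frozen=True)
class BindingSite:
    """A specific binding site on the synthetic substrate."""

    name: str
    start: int  # 1-based inclusive
    end: int
    ka: float  # true association constant, nM^-1

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic-data generators, with study defaults.

    Cleavage-dataset side: ``n_pairs`` pairs of length ``guide_length`` at
    ``gc_fraction``; one canonical mismatch per pair at a PAM-distal
    position (>= ``mismatch_min_position``); cutting frequency =
    logistic(link_intercept + link_slope * true_stability) + N(0, noise_sd),
    redrawn (truncated) at 0.  The stability metric uses the standard KMC
    settings (m0 = 10, 1000 replicates, max_t = 100, m* = 16).

    Binding side: ``n_molecules`` substrates of ``substrate_length`` bp with
    ``sites`` at known Ka; footprint centers broadened by ``position_sigma``
    (bp); ``background_rate`` nonspecific proteins per molecule (Poisson).
    """

    seed: int = 0
    # guide/target pairs
    n_pairs: int = 60
    guide_length: int = 20
    gc_fraction: float = 0.5
    mismatch_min_position: int = 10
    # stability -> frequency link
    link: str = "logistic"  # or "identity"
    link_slope: float = 6.0
    link_intercept: float = -3.0
    noise_sd: float = 0.1
    # KMC settings for the true stability
    m_star: int = 16
    kmc_reps: int = 1000
    kmc_m0: int = 10
    kmc_max_t: float = 100.0
    # binding datasets
    n_molecules: int = 500
    substrate_length: int = 989
    sites: tuple[BindingSite, ...] = (BindingSite("full_site", 144, 167, 0.05),)
    position_sigma: float = 40.0
    footprint_length: int = 78
    background_rate: float = 0.2
    protein0: float = 50.0
    dna0: float = 2.5

    def __post_init__(self):
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.position_sigma <= 0 or self.noise_sd < 0:
            raise ValueError("position_sigma must be > 0 and noise_sd >= 0")


def _rng(spec: GeneratorSpec, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), *map(int, stream)]))


def make_pair(spec: GeneratorSpec, index: int) -> GuideTargetPair:
    """Random perfectly-complementary guide/protospacer pair (NGG PAM).

    Deterministic under (spec.seed, index); base identities drawn per
    position with the requested GC fraction.
    """
    rng = _rng(spec, 0, index)
    bases = []
    for _ in range(spec.guide_length):
        if rng.random() < spec.gc_fraction:
            bases.append("G" if rng.random() < 0.5 else "C")
        else:
            bases.append("A" if rng.random() < 0.5 else "U")
    guide = "".join(bases)
    proto = guide.replace("U", "T")
    pam = rng.choice(list("ACGT")) + "GG"
    return GuideTargetPair(guide=guide, protospacer=proto, pam=pam)


def inject_mismatch(pair: GuideTargetPair, position: int, mm_type: str) -> GuideTargetPair:
    """Substitute one bound-strand base to create a canonical mismatch.

    ``mm_type`` (rG.dG / rC.dC / rA.dA / rU.dT) is achievable only where the
    guide base equals its RNA letter; the target-strand substitution is
    applied on the stored guide-matching strand via complementation.
    Raises if the position is already mismatched or the type unachievable.
    """
    if mm_type not in _INJECTION:
        raise ValueError(f"unknown mismatch type {mm_type!r}")
    need_guide, new_bound = _INJECTION[mm_type]
    if not pair.is_matched(position):
        raise ValueError(f"position {position} is already mismatched")
    g = pair.guide_base(position)
    if g != need_guide:
        raise ValueError(
            f"{mm_type} requires guide base {need_guide} at position {position}, found {g}"
        )
    proto = list(pair.protospacer)
    proto[len(proto) - position] = DNA_COMPLEMENT[new_bound]
    return GuideTargetPair(guide=pair.guide, protospacer="".join(proto), pam=pair.pam)


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def synth_cleavage_dataset(
    spec: GeneratorSpec, model: EnergyModel | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic single-mismatch cleavage dataset plus its ground truth.

    Each record is a random pair with one injected canonical PAM-distal
    mismatch; its true R-loop stability is simulated with the generator's
    own seed stream, and the observed cutting frequency is the logistic
    link of that stability plus truncated Gaussian noise (redrawn while
    negative).  Returns (observed, truth) DataFrames; ``observed`` has the
    pipeline input columns, ``truth`` everything needed to recompute the
    expected estimates.
    """
    model = model or load_energy_model()
    rng = _rng(spec, 1)
    obs_rows, truth_rows = [], []
    for i in range(spec.n_pairs):
        pair = make_pair(spec, i)
        pos = int(rng.integers(spec.mismatch_min_position, spec.guide_length + 1))
        mm_type = _TYPE_FOR_GUIDE_BASE[pair.guide_base(pos)]
        mutated = inject_mismatch(pair, pos, mm_type)
        true_seed = int(_rng(spec, 2, i).integers(0, 2**31))
        occ = stability_metric(
            mutated,
            model,
            m_star=spec.m_star,
            reps=spec.kmc_reps,
            m0=spec.kmc_m0,
            max_t=spec.kmc_max_t,
            seed=true_seed,
        )
        linear = spec.link_intercept + spec.link_slope * occ.mean_frac
        if spec.link == "logistic":
            expected = float(_logistic(linear))
        elif spec.link == "identity":
            expected = float(linear)
        else:
            raise ValueError(f"unknown link {spec.link!r}")
        freq = -1.0
        while freq < 0:
            freq = expected + rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else expected
        rec_id = f"synth{i:04d}"
        obs_rows.append(
            dict(
                guide_id=rec_id,
                guide_seq=mutated.guide,
                target_seq=mutated.protospacer,
                cutting_frequency=freq,
            )
        )
        truth_rows.append(
            dict(
                guide_id=rec_id,
                mismatch_position=pos,
                mismatch_type=mm_type,
                true_stability=occ.mean_frac,
                true_stability_sem=occ.sem,
                expected_frequency=expected,
                link_slope=spec.link_slope,
                link_intercept=spec.link_intercept,
                noise_sd=spec.noise_sd,
            )
        )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


def cleavage_records(observed: pd.DataFrame) -> list[SpecificityRecord]:
    """Wrap an observed cleavage table into pipeline records."""
    return [
        SpecificityRecord(
            record_id=str(r.guide_id),
            pair=GuideTargetPair(guide=r.guide_seq, protospacer=r.target_seq),
            cutting_frequency=float(r.cutting_frequency),
        )
        for r in observed.itertuples(index=False)
    ]


def _free_protein(spec: GeneratorSpec) -> float:
    """Self-consistent free-protein concentration (nM) at equilibrium."""
    free = spec.protein0
    for _ in range(100):
        occ = sum(s.ka * free / (1.0 + s.ka * free) for s in spec.sites)
        new = spec.protein0 - spec.dna0 * (occ + spec.background_rate)
        if new <= 0:
            raise ValueError("protein depleted: reduce dna0, sites or background")
        if abs(new - free) < 1e-12:
            break
        free = new
    return free


def synth_binding_dataset(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Synthetic binding-event table plus ground truth.

    Per molecule, each site is occupied with the isotherm probability
    theta = Ka*[P]free / (1 + Ka*[P]free) at the self-consistent free
    concentration; footprint centers get Gaussian position noise; a
    Poisson number of background proteins bind uniformly.  Returns an
    events DataFrame (columns dna_id, contact_start, contact_end,
    contact_index, n_contacts) and a ground-truth dict.
    """
    rng = _rng(spec, 3)
    free = _free_protein(spec)
    thetas = {s.name: s.ka * free / (1.0 + s.ka * free) for s in spec.sites}
    half = spec.footprint_length // 2
    L = spec.substrate_length
    rows = []
    bound_counts = np.zeros(spec.n_molecules, dtype=int)
    for i in range(spec.n_molecules):
        dna_id = f"mol{i:05d}"
        centers = []
        for s in spec.sites:
            if rng.random() < thetas[s.name]:
                centers.append(s.center + rng.normal(0.0, spec.position_sigma))
        for _ in range(rng.poisson(spec.background_rate)):
            centers.append(rng.uniform(1, L))
        bound_counts[i] = len(centers)
        for c in centers:
            lo = int(np.clip(round(c) - half, 1, L))
            hi = int(np.clip(round(c) + half, 1, L))
            if hi < lo:
                lo, hi = hi, lo
            rows.append(
                dict(dna_id=dna_id, contact_start=lo, contact_end=hi, contact_index=1, n_contacts=1)
            )
    events = pd.DataFrame(rows, columns=["dna_id", "contact_start", "contact_end", "contact_index", "n_contacts"])
    truth = dict(
        free_protein=free,
        site_theta=thetas,
        site_kd={s.name: 1.0 / s.ka for s in spec.sites},
        site_ka={s.name: s.ka for s in spec.sites},
        position_sigma=spec.position_sigma,
        expected_w=float(np.sqrt(2.0) * spec.position_sigma),
        background_rate=spec.background_rate,
        protein0=spec.protein0,
        dna0=spec.dna0,
        n_molecules=spec.n_molecules,
        bound_counts=bound_counts.tolist(),
    )
    return events, truth


def events_from_frame(events: pd.DataFrame):
    """Group an events table into :class:`~rloopkmc.binding_model.BindingEvent`s.

    Rows sharing (dna_id, and consecutive contact_index of one protein) are
    one protein; in the synthetic tables each row is one single-contact
    protein.
    """
    from .binding_model import BindingEvent

    out = []
    for row in events.itertuples(index=False):
        n = int(getattr(row, "n_contacts", 1))
        if n == 1:
            out.append(BindingEvent(dna_id=str(row.dna_id), contacts=((int(row.contact_start), int(row.contact_end)),)))
        else:
            out.append(row)  # multi-contact rows handled by the caller's grouping
    return out


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_cleavage_dataset(spec: GeneratorSpec, out_dir, model: EnergyModel | None = None):
    """Write observed TSV, ground-truth TSV, and guide/target FASTA files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    observed, truth = synth_cleavage_dataset(spec, model)
    observed.to_csv(out / "cleavage_observed.tsv", sep="\t", index=False)
    truth.to_csv(out / "cleavage_truth.tsv", sep="\t", index=False)
    with open(out / "guides.fasta", "w") as fh:
        for r in observed.itertuples(index=False):
            fh.write(f">{r.guide_id}\n{r.guide_seq}\n")
    with open(out / "targets.fasta", "w") as fh:
        for r in observed.itertuples(index=False):
            fh.write(f">{r.guide_id}\n{r.target_seq}\n")
    return observed, truth


def write_binding_dataset(spec: GeneratorSpec, out_dir):
    """Write the events TSV and the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events, truth = synth_binding_dataset(spec)
    events.to_csv(out / "binding_events.tsv", sep="\t", index=False)
    with open(out / "binding_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return events, truth


def spec_from_yaml(path) -> GeneratorSpec:
    """Load a :class:`GeneratorSpec` from a YAML file.

    Top-level keys mirror the dataclass fields; ``sites`` is a list of
    ``{name, start, end, ka}`` mappings.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "sites" in raw:
        raw["sites"] = tuple(BindingSite(**s) for s in raw["sites"])
    return GeneratorSpec(**raw)
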