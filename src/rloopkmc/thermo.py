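"""Nearest-neighbour thermodynamics of guide-RNA / protospacer hybridization.

The R-loop model treats strand invasion as the stepwise replacement of
DNA:DNA base pairs by RNA:DNA base pairs.  Everything downstream (rates,
stationary occupancies, binding free energies) reduces to the per-position
exchange free energy

    ddG(m) = dG37(m)_RNA:DNA - dG37(m)_DNA:DNA    [kcal/mol]

where the nearest-neighbour stack spanning protospacer positions (m-1, m)
is attributed to position m and position 1 carries no stack energy (duplex
initiation is handled separately).  Positions are counted 1..N from the
PAM-proximal end of the protospacer; negative ddG favours invasion.

Parameter tables (Watson-Crick DNA:DNA and RNA:DNA doublets plus
mismatch-containing doublets for the four canonical rG.dG, rC.dC, rA.dA,
rU.dT mismatches) are data, loaded from a JSON file, so alternative
parameter sets can be swapped in without touching code.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

GAS_CONSTANT_KCAL = 1.987e-3  # kcal / (mol K)

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: DNA base that pairs (Watson-Crick) with each RNA base in a hybrid duplex
RNA_TO_DNA_PARTNER = {"A": "T", "U": "A", "C": "G", "G": "C"}

#: canonical single-mismatch classes with characterized thermodynamics
CANONICAL_MISMATCHES = ("rG.dG", "rC.dC", "rA.dA", "rU.dT")

#: AAVS1 "T2" target site (human chromosome 19, PPP1R12C intron 1); the
#: protospacer is written 5'->3' on the strand whose sequence matches the
#: guide, with the NGG PAM immediately 3' of it.
AAVS1_PROTOSPACER = "GGGGCCACTAGGGACAGGAT"
AAVS1_PAM = "TGG"
#: 20-nt single-guide RNA targeting AAVS1 (same sequence as the protospacer,
#: T -> U) and its 2-nt 5'-truncated variant (tru-gRNA, 18 nt).
AAVS1_SGRNA = AAVS1_PROTOSPACER.replace("T", "U")
AAVS1_TRU_GRNA = AAVS1_SGRNA[2:]


class MissingParameterError(KeyError):
    """A nearest-neighbour context has no entry in the loaded tables."""


def normalize_sequence(seq: str, molecule: str) -> str:
    """Upper-case a sequence and normalize T/U for the molecule type.

    ``molecule`` is ``"rna"`` (T -> U, warning logged) or ``"dna"`` (U -> T).
    Raises ``ValueError`` naming the first illegal character.
    """
    seq = str(seq).strip().upper()
    if molecule == "rna":
        if "T" in seq:
            logger.warning("RNA sequence contains T; normalizing to U")
            seq = seq.replace("T", "U")
        alphabet = RNA_ALPHABET
    elif molecule == "dna":
        seq = seq.replace("U", "T")
        alphabet = DNA_ALPHABET
    else:
        raise ValueError(f"molecule must be 'rna' or 'dna', got {molecule!r}")
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"illegal {molecule.upper()} character {ch!r} at position {i + 1}"
            )
    return seq


def dna_complement(seq: str) -> str:
    """Base-wise complement of a DNA string (no reversal)."""
    return "".join(DNA_COMPLEMENT[b] for b in seq)


def reverse_complement(seq: str) -> str:
    return dna_complement(seq)[::-1]


def classify_mismatch(guide_base: str, bound_base: str) -> str:
    """Classify a guide-RNA base opposite a target(bound)-strand DNA base.

    Returns one of the four canonical classes ``rG.dG``/``rC.dC``/``rA.dA``/
    ``rU.dT`` or ``"other"``.  Raises ``ValueError`` if the pair is
    Watson-Crick (not a mismatch).
    """
    if RNA_TO_DNA_PARTNER[guide_base] == bound_base:
        raise ValueError(f"r{guide_base}.d{bound_base} is Watson-Crick, not a mismatch")
    label = f"r{guide_base}.d{bound_base}"
    return label if label in CANONICAL_MISMATCHES else "other"


@dataclass(frozen=True)
class GuideTargetPair:
    """A guide RNA aligned to a protospacer duplex, indexed from the PAM.

    ``protospacer`` is written 5'->3' on the strand whose sequence matches
    the guide; the PAM follows its 3' end, so protospacer position ``m``
    (1..N, PAM-proximal first) is the character ``protospacer[-m]``.  The
    guide pairs with the *other* (bound) DNA strand; its 3' end engages
    position 1.  ``mismatches`` holds ``(position, class)`` for every
    position where the guide base does not complement the bound strand.
    """

    guide: str
    protospacer: str
    pam: str = "TGG"
    mismatches: tuple[tuple[int, str], ...] = field(init=False)

    def __post_init__(self):
        guide = normalize_sequence(self.guide, "rna")
        proto = normalize_sequence(self.protospacer, "dna")
        pam = normalize_sequence(self.pam, "dna")
        object.__setattr__(self, "guide", guide)
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam", pam)
        if not 16 <= len(guide) <= 20:
            raise ValueError(f"guide length must be 16..20 nt, got {len(guide)}")
        if len(proto) < len(guide):
            raise ValueError("protospacer shorter than guide")
        if len(pam) != 3:
            raise ValueError("PAM must be 3 nt")
        mm = []
        for m in range(1, len(guide) + 1):
            g = self.guide_base(m)
            d = self.bound_strand_base(m)
            if RNA_TO_DNA_PARTNER[g] != d:
                mm.append((m, classify_mismatch(g, d)))
        object.__setattr__(self, "mismatches", tuple(mm))

    @property
    def n(self) -> int:
        """Number of interacting positions (guide length)."""
        return len(self.guide)

    def guide_base(self, m: int) -> str:
        """Guide base pairing protospacer position ``m`` (1 = PAM-proximal)."""
        self._check_position(m)
        return self.guide[len(self.guide) - m]

    def protospacer_base(self, m: int) -> str:
        """Letter of the guide-matching DNA strand at position ``m``."""
        self._check_position(m)
        return self.protospacer[len(self.protospacer) - m]

    def bound_strand_base(self, m: int) -> str:
        """Letter of the DNA strand the guide actually base-pairs with."""
        return DNA_COMPLEMENT[self.protospacer_base(m)]

    def is_matched(self, m: int) -> bool:
        return all(pos != m for pos, _ in self.mismatches)

    def _check_position(self, m: int) -> None:
        if not 1 <= m <= self.n:
            raise ValueError(f"position {m} outside 1..{self.n}")


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbour dG37 tables plus initiation term and conditions.

    All energies in kcal/mol; more negative = more stable.  ``nn_dna_dna``
    holds the 10 unique Watson-Crick DNA:DNA doublets (the rest resolve via
    reverse-complement identity); ``nn_rna_dna`` the 16 hybrid doublets
    keyed by the RNA strand 5'->3'; ``nn_mismatch`` mismatch-containing
    hybrid doublets keyed ``"XY/VW"`` (guide RNA doublet over the aligned
    bound-strand DNA bases).
    """

    nn_dna_dna: Mapping[str, float]
    nn_rna_dna: Mapping[str, float]
    nn_mismatch: Mapping[str, float]
    dg_init: float = -3.1
    temperature: float = 310.15
    gas_constant: float = GAS_CONSTANT_KCAL
    salt_label: str = "1 M NaCl"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name, table in (
            ("nn_dna_dna", self.nn_dna_dna),
            ("nn_rna_dna", self.nn_rna_dna),
            ("nn_mismatch", self.nn_mismatch),
        ):
            for key, val in table.items():
                if not (val == val and abs(val) < 1e6):
                    raise ValueError(f"{name}[{key}] is not finite")
        # completeness: every Watson-Crick context must resolve
        for a in "ACGT":
            for b in "ACGT":
                self.dna_step(a + b)
        for a in "ACGU":
            for b in "ACGU":
                self.hybrid_step(a + b)
        # sanity on the sign convention: a fully stacked GC-rich duplex is stable
        if self.nn_dna_dna.get("GC", -1.0) > 0:
            raise ValueError("DNA:DNA table violates the negative-is-stable convention")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    def dna_step(self, doublet: str) -> float:
        """dG37 of a Watson-Crick DNA:DNA doublet (either orientation)."""
        if doublet in self.nn_dna_dna:
            return float(self.nn_dna_dna[doublet])
        rc = reverse_complement(doublet)
        if rc in self.nn_dna_dna:
            return float(self.nn_dna_dna[rc])
        raise MissingParameterError(f"DNA:DNA doublet {doublet!r} not parameterized")

    def hybrid_step(self, rna_doublet: str) -> float:
        """dG37 of a Watson-Crick RNA:DNA doublet, keyed by the RNA strand."""
        try:
            return float(self.nn_rna_dna[rna_doublet])
        except KeyError:
            raise MissingParameterError(
                f"RNA:DNA doublet {rna_doublet!r} not parameterized"
            ) from None

    def mismatch_step(self, rna_doublet: str, dna_doublet: str, *, terminal: bool = False) -> float:
        """dG37 of a mismatch-containing hybrid doublet.

        ``dna_doublet`` is the bound-strand DNA bases aligned opposite the
        guide doublet.  If the exact context is missing and ``terminal`` is
        set, the value falls back to the nearest internal context (any entry
        with the same mismatched pair) with a logged warning.
        """
        key = f"{rna_doublet}/{dna_doublet}"
        if key in self.nn_mismatch:
            return float(self.nn_mismatch[key])
        if terminal:
            for cand, val in self.nn_mismatch.items():
                if cand.startswith(rna_doublet[0]) and cand.split("/")[1][0] == dna_doublet[0]:
                    warnings.warn(
                        f"terminal mismatch context {key} missing; "
                        f"falling back to internal context {cand}",
                        stacklevel=2,
                    )
                    return float(val)
        raise MissingParameterError(f"mismatch doublet {key!r} not parameterized")


def load_energy_model(path: str | Path | None = None, **overrides) -> EnergyModel:
    """Load an :class:`EnergyModel` from a JSON parameter file.

    With no ``path``, the packaged parameter set (1 M NaCl, 37 C) is used.
    Keyword overrides (e.g. ``dg_init=0.0``) replace the file's values.
    """
    if path is None:
        text = resources.files("rloopkmc.data").joinpath("nn_params.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    kwargs = dict(
        nn_dna_dna=raw["dna_dna"],
        nn_rna_dna=raw["rna_dna"],
        nn_mismatch=raw.get("mismatch", {}),
        dg_init=raw.get("dg_init", -3.1),
        temperature=raw.get("temperature_K", 310.15),
        gas_constant=raw.get("gas_constant_kcal_per_mol_K", GAS_CONSTANT_KCAL),
        salt_label=raw.get("salt_label", ""),
    )
    kwargs.update(overrides)
    return EnergyModel(**kwargs)


def _step_doublets(pair: GuideTargetPair, m: int) -> tuple[str, str, str]:
    """(guide RNA doublet, protospacer DNA doublet, bound-strand doublet)
    for the stack spanning positions (m, m-1), each written 5'->3' on the
    guide-matching strand (position m first)."""
    g = pair.guide_base(m) + pair.guide_base(m - 1)
    p = pair.protospacer_base(m) + pair.protospacer_base(m - 1)
    b = pair.bound_strand_base(m) + pair.bound_strand_base(m - 1)
    return g, p, b


def hybrid_step_energy(pair: GuideTargetPair, m: int, model: EnergyModel) -> float:
    """RNA:DNA dG37 attributed to position m (stack spanning m-1, m)."""
    pair._check_position(m)
    if m == 1:
        return 0.0
    g, _, b = _step_doublets(pair, m)
    if pair.is_matched(m) and pair.is_matched(m - 1):
        return model.hybrid_step(g)
    terminal = m == pair.n or m - 1 == 1
    return model.mismatch_step(g, b, terminal=terminal)


def dna_step_energy(pair: GuideTargetPair, m: int, model: EnergyModel) -> float:
    """DNA:DNA dG37 attributed to position m.

    The genomic duplex is fully Watson-Crick regardless of guide mismatches
    (a mismatch lives only in the hybrid), so this is always a plain lookup.
    """
    pair._check_position(m)
    if m == 1:
        return 0.0
    _, p, _ = _step_doublets(pair, m)
    return model.dna_step(p)


def step_exchange_energy(pair: GuideTargetPair, m: int, model: EnergyModel) -> float:
    """ddG(m) = dG37(m)_RNA:DNA - dG37(m)_DNA:DNA, kcal/mol."""
    return hybrid_step_energy(pair, m, model) - dna_step_energy(pair, m, model)


def exchange_energy_profile(pair: GuideTargetPair, model: EnergyModel):
    """Vector [ddG(1), ..., ddG(N)] (ddG(1) = 0 by convention)."""
    import numpy as np

    return np.array(
        [step_exchange_energy(pair, m, model) for m in range(1, pair.n + 1)]
    )


def duplex_binding_energy(
    pair: GuideTargetPair, model: EnergyModel, *, include_init: bool = True
) -> float:
    """Total guide-protospacer hybridization dG37 (kcal/mol).

    Sum of the mismatch-aware RNA:DNA nearest-neighbour step energies plus
    the duplex initiation term (default -3.1 kcal/mol, configurable).
    """
    total = sum(hybrid_step_energy(pair, m, model) for m in range(2, pair.n + 1))
    if include_init:
        total += model.dg_init
    return total


def dna_duplex_energy(pair: GuideTargetPair, model: EnergyModel) -> float:
    """Total DNA:DNA stack energy over the interacting region (no initiation)."""
    return sum(dna_step_energy(pair, m, model) for m in range(2, pair.n + 1))
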