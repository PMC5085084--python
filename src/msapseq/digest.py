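"""In-silico MSAP digestion engine.

Methylation-sensitive amplified polymorphism (MSAP) reads cytosine
methylation at CCGG sites as band presence/absence: genomic DNA is
double-digested with EcoRI plus one of the isoschizomers HpaII or MspI,
adaptor-ligated, and selectively amplified.  The two isoschizomers
recognise the same CCGG tetranucleotide but differ in their sensitivity
to cytosine methylation, so comparing the two digestion channels of the
same sample reveals the methylation state of each site.

This module locates restriction sites, applies the methylation-dependent
cleavage rules, performs the double digestion, and applies the selective
amplification step to predict the MSAP amplicon spectrum of a genome +
methylome.

Cleavage rules implemented (site-level, six states):

===============  =====  ======
state            MspI   HpaII
===============  =====  ======
CCGG (none)      cut    cut
hemi  CmCGG      cut    --
full  CmCGG      cut    --
hemi  mCCGG      --     cut
full  mCCGG      --     --
mCmCGG (double)  --     --
===============  =====  ======

EcoRI (GAATTC) is modelled as methylation-insensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Enzyme",
    "Channel",
    "FragmentEnd",
    "MethylationState",
    "Methylome",
    "RestrictionFragment",
    "PrimerCombo",
    "AmpliconRecord",
    "DEFAULT_COMBOS",
    "DEFAULT_SIZE_WINDOW",
    "classify_cleavage",
    "find_sites",
    "double_digest",
    "select_amplicons",
    "predicted_amplicons",
    "predicted_spectrum",
    "revcomp",
]

ECORI_MOTIF = "GAATTC"
CCGG_MOTIF = "CCGG"
#: cut placed after this offset within the motif (G^AATTC, C^CGG)
ECORI_CUT_OFFSET = 1
CCGG_CUT_OFFSET = 1

#: detectable fragment-analyser size window in bp (GeneScan 500 standard)
DEFAULT_SIZE_WINDOW = (50, 500)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Enzyme(str, Enum):
    MSPI = "MSPI"
    HPAII = "HPAII"
    ECORI = "ECORI"


class Channel(str, Enum):
    """A digestion channel: EcoRI + MspI, or EcoRI + HpaII."""

    MSP = "MSP"
    HPA = "HPA"

    @property
    def enzyme(self) -> Enzyme:
        return Enzyme.MSPI if self is Channel.MSP else Enzyme.HPAII


class FragmentEnd(str, Enum):
    ECORI = "ECORI"
    HH = "HH"  # HpaII/MspI (CCGG) cut
    TERMINUS = "TERMINUS"


class MethylationState(str, Enum):
    """Site-level methylation state of one CCGG tetranucleotide.

    INTERNAL refers to the inner cytosine (CmCGG), EXTERNAL to the outer
    one (mCCGG); HEMI = one strand methylated, FULL = both; DOUBLE =
    both cytosines methylated (mCmCGG).
    """

    NONE = "NONE"
    HEMI_INTERNAL = "HEMI_INTERNAL"
    FULL_INTERNAL = "FULL_INTERNAL"
    HEMI_EXTERNAL = "HEMI_EXTERNAL"
    FULL_EXTERNAL = "FULL_EXTERNAL"
    DOUBLE = "DOUBLE"


_MSPI_CUTS = frozenset(
    {MethylationState.NONE, MethylationState.HEMI_INTERNAL, MethylationState.FULL_INTERNAL}
)
_HPAII_CUTS = frozenset({MethylationState.NONE, MethylationState.HEMI_EXTERNAL})


def classify_cleavage(enzyme: Enzyme | str, state: MethylationState | str) -> bool:
    """Whether `enzyme` cleaves a CCGG site in the given methylation state.

    MspI tolerates internal-cytosine methylation (cuts CCGG, hemi/full
    CmCGG); HpaII cuts only unmethylated CCGG and hemimethylated mCCGG;
    neither cuts the doubly methylated site.  EcoRI is treated as
    methylation-insensitive and always cuts (the state argument is
    ignored).
    """
    enzyme = Enzyme(enzyme)
    state = MethylationState(state)
    if enzyme is Enzyme.ECORI:
        return True
    if enzyme is Enzyme.MSPI:
        return state in _MSPI_CUTS
    return state in _HPAII_CUTS


@dataclass(frozen=True)
class Methylome:
    """Per-CCGG-site methylation annotation for one genome.

    Maps the 0-based position of the first C of each annotated CCGG to a
    :class:`MethylationState`.  Sites not annotated default to NONE
    during digestion.
    """

    states: Mapping[int, MethylationState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "states",
            {int(p): MethylationState(s) for p, s in dict(self.states).items()},
        )

    def validate_against(self, sequence: str) -> None:
        """Raise ValueError unless every annotated position starts CCGG."""
        seq = sequence.upper()
        for pos in self.states:
            if not 0 <= pos <= len(seq) - 4 or seq[pos : pos + 4] != CCGG_MOTIF:
                raise ValueError(f"position {pos} does not begin a CCGG in the sequence")

    def state_at(self, pos: int) -> MethylationState:
        return self.states.get(pos, MethylationState.NONE)

    def with_state(self, pos: int, state: MethylationState) -> "Methylome":
        new = dict(self.states)
        new[pos] = MethylationState(state)
        return Methylome(new)


@dataclass(frozen=True)
class RestrictionFragment:
    """One fragment of a double digest, in 0-based half-open coordinates."""

    start: int
    end: int
    left_end: FragmentEnd
    right_end: FragmentEnd
    sequence: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("fragment start must be < end")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("fragment sequence length disagrees with coordinates")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerCombo:
    """A selective-amplification primer combination.

    ``ecoRI_selective`` is the 3-base 3' extension of the EcoRI primer,
    ``hh_selective`` the 4-base extension of the HpaII/MspI primer.
    """

    id: str
    ecoRI_selective: str
    hh_selective: str
    dye: str = ""

    def __post_init__(self) -> None:
        for attr, n in (("ecoRI_selective", 3), ("hh_selective", 4)):
            val = getattr(self, attr).upper()
            if len(val) != n or set(val) - set("ACGT"):
                raise ValueError(f"{attr} must be {n} bases over ACGT, got {val!r}")
            object.__setattr__(self, attr, val)


#: The nine EcoRI x HpaII/MspI selective-primer combinations (I-IX):
#: EcoRI-AGG (FAM), EcoRI-ACT (JOE), EcoRI-AGC (NED) crossed with
#: HpaII/MspI-GCAT, -TCGC, -TCAA.
DEFAULT_COMBOS: tuple[PrimerCombo, ...] = (
    PrimerCombo("I", "AGG", "GCAT", "FAM"),
    PrimerCombo("II", "ACT", "GCAT", "JOE"),
    PrimerCombo("III", "AGC", "GCAT", "NED"),
    PrimerCombo("IV", "AGG", "TCGC", "FAM"),
    PrimerCombo("V", "ACT", "TCGC", "JOE"),
    PrimerCombo("VI", "AGC", "TCGC", "NED"),
    PrimerCombo("VII", "AGG", "TCAA", "FAM"),
    PrimerCombo("VIII", "ACT", "TCAA", "JOE"),
    PrimerCombo("IX", "AGC", "TCAA", "NED"),
)


@dataclass(frozen=True)
class AmpliconRecord:
    """A predicted (or observed) selective-amplification product."""

    combo_id: str
    channel: Channel
    size_bp: int
    sequence: str
    source: tuple[str, int, int]  # (genome id, start, end)


def find_sites(sequence: str) -> tuple[list[int], list[int]]:
    """Locate EcoRI (GAATTC) and CCGG motif starts on the reference strand.

    Both motifs cut identically on either strand, so scanning the
    reference strand suffices.  Overlapping occurrences are all
    reported; windows containing N never match.  Returns
    ``(ecoRI_starts, ccgg_starts)``, 0-based.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A/C/G/T/N")
    ecoRI = [m.start() for m in re.finditer(f"(?={ECORI_MOTIF})", seq)]
    ccgg = [m.start() for m in re.finditer(f"(?={CCGG_MOTIF})", seq)]
    return ecoRI, ccgg


def double_digest(
    sequence: str,
    methylome: Methylome | None,
    channel: Channel | str,
) -> list[RestrictionFragment]:
    """Double-digest a sequence with EcoRI plus the channel isoschizomer.

    EcoRI cuts G^AATTC at every site; the CCGG enzyme cuts C^CGG only
    where :func:`classify_cleavage` allows it for the site's methylation
    state (unannotated sites are unmethylated).  Fragments are the
    maximal intervals between consecutive cuts; the sequence termini are
    labelled TERMINUS.
    """
    channel = Channel(channel)
    methylome = methylome or Methylome()
    seq = sequence.upper()
    methylome.validate_against(seq)
    ecoRI_sites, ccgg_sites = find_sites(seq)

    cuts: dict[int, FragmentEnd] = {}
    for s in ecoRI_sites:
        cuts[s + ECORI_CUT_OFFSET] = FragmentEnd.ECORI
    enzyme = channel.enzyme
    for s in ccgg_sites:
        if classify_cleavage(enzyme, methylome.state_at(s)):
            cuts[s + CCGG_CUT_OFFSET] = FragmentEnd.HH

    bounds = sorted(p for p in cuts if 0 < p < len(seq))
    fragments: list[RestrictionFragment] = []
    prev = 0
    prev_end = FragmentEnd.TERMINUS
    for p in bounds + [len(seq)]:
        right = cuts.get(p, FragmentEnd.TERMINUS) if p < len(seq) else FragmentEnd.TERMINUS
        if p > prev:
            fragments.append(
                RestrictionFragment(prev, p, prev_end, right, seq[prev:p])
            )
        prev, prev_end = p, right
    return fragments


def _selective_match(fragment: RestrictionFragment, combo: PrimerCombo) -> bool:
    """Selective-base test for a mixed-end (one EcoRI, one HH) fragment.

    Convention (single, configurable-by-replacement): with the EcoRI cut
    on the left the fragment starts with the AATTC remnant and the three
    bases after it must equal the EcoRI selective triplet; with the HH
    cut on the right the fragment ends with the outer C of CCGG and the
    four top-strand bases immediately before it must equal the
    HpaII/MspI selective tetramer.  Mirror-orientation ends are compared
    through the reverse complement.
    """
    seq = fragment.sequence
    if fragment.left_end is FragmentEnd.ECORI:
        # AATTC remnant (5) + 3 selective bases
        if len(seq) < 5 + 3 or seq[5:8] != combo.ecoRI_selective:
            return False
    elif fragment.left_end is FragmentEnd.HH:
        # CGG remnant (3) + 4 selective bases, read on the bottom strand
        if len(seq) < 3 + 4 or revcomp(seq[3:7]) != combo.hh_selective:
            return False
    if fragment.right_end is FragmentEnd.ECORI:
        # fragment ends with the G of G^AATTC; triplet read on bottom strand
        if len(seq) < 1 + 3 or revcomp(seq[-4:-1]) != combo.ecoRI_selective:
            return False
    elif fragment.right_end is FragmentEnd.HH:
        # fragment ends with the outer C of C^CGG
        if len(seq) < 1 + 4 or seq[-5:-1] != combo.hh_selective:
            return False
    return True


def select_amplicons(
    fragments: Iterable[RestrictionFragment],
    combo: PrimerCombo,
    genome_id: str = "",
    *,
    channel: Channel | str = Channel.MSP,
    adaptor_offset: int = 0,
    size_window: tuple[int, int] = DEFAULT_SIZE_WINDOW,
) -> list[AmpliconRecord]:
    """Apply selective amplification to digest fragments.

    Only fragments with exactly one EcoRI end and one HpaII/MspI end are
    amplifiable (only the EcoRI primer carries a dye, so double-HH and
    double-EcoRI products are invisible).  A fragment is retained iff
    both selective-base extensions match (see :func:`_selective_match`).
    ``size_bp`` is the fragment length plus a constant adaptor/primer
    offset; amplicons outside the detectable window are dropped.
    """
    channel = Channel(channel)
    lo, hi = size_window
    out: list[AmpliconRecord] = []
    for frag in fragments:
        ends = {frag.left_end, frag.right_end}
        if ends != {FragmentEnd.ECORI, FragmentEnd.HH}:
            continue
        if not _selective_match(frag, combo):
            continue
        size = len(frag) + adaptor_offset
        if not lo <= size <= hi:
            continue
        out.append(
            AmpliconRecord(
                combo_id=combo.id,
                channel=channel,
                size_bp=size,
                sequence=frag.sequence,
                source=(genome_id, frag.start, frag.end),
            )
        )
    return out


def predicted_amplicons(
    genome: str,
    methylome: Methylome | None,
    combo: PrimerCombo,
    channel: Channel | str,
    *,
    genome_id: str = "",
    adaptor_offset: int = 0,
    size_window: tuple[int, int] = DEFAULT_SIZE_WINDOW,
) -> list[AmpliconRecord]:
    """Full in-silico MSAP prediction: digest then selective amplification."""
    frags = double_digest(genome, methylome, channel)
    return select_amplicons(
        frags,
        combo,
        genome_id,
        channel=channel,
        adaptor_offset=adaptor_offset,
        size_window=size_window,
    )


def predicted_spectrum(
    genome: str,
    methylome: Methylome | None,
    combo: PrimerCombo,
    channel: Channel | str,
    **kwargs,
) -> list[int]:
    """Predicted band sizes (bp) for one combo/channel, sorted, comigrating
    duplicates collapsed."""
    records = predicted_amplicons(genome, methylome, combo, channel, **kwargs)
    return sorted({r.size_bp for r in records})
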