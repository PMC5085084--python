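"""Synthetic cultivar/somaclone genomes with planted methylation changes.

The generator emulates the study design the pipeline targets: two
unrelated "cultivar" genomes, each with a background CCGG methylome and
a derived "somaclone" methylome that differs at planted CCGG sites, a
configurable subset of which sits in an identical sequence cassette
shared between the two cultivars (the analogue of a region that changes
repeatedly under in vitro cultivation).  Pooled, MID-barcoded,
error-bearing amplicon reads are simulated from the predicted MSAP
amplicons, and every planted change is recorded in a machine-readable
truth set for parameter-recovery testing.

Genomes are assembled from random motif-free spacers and explicit
*amplicon cassettes*::

    GAATTC  e_sel(3)  insert  h_sel(4)  CCGG

so that each cassette yields exactly one selective amplicon for exactly
one primer combination, controlled by the methylation state of its CCGG
site.  The assembly is scrubbed so that no other fragment anywhere in
the genome passes selective amplification; predicted spectra are
therefore exactly the cassette bands, which makes every planted flip's
expected band change recomputable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .contigs import DEFAULT_MID_TABLE, SequencedRead
from .digest import (
    CCGG_MOTIF,
    DEFAULT_COMBOS,
    ECORI_MOTIF,
    AmpliconRecord,
    Channel,
    MethylationState,
    Methylome,
    PrimerCombo,
    classify_cleavage,
    find_sites,
    predicted_amplicons,
    revcomp,
)

__all__ = [
    "SimulationConfig",
    "CassetteRecord",
    "GenomeBuild",
    "TruthRecord",
    "SyntheticExperiment",
    "make_genome",
    "derive_somaclone",
    "simulate_reads",
    "simulate_experiment",
]

_BASES = np.array(list("ACGT"))

#: states under which a CCGG site yields an amplicon in >=1 channel
_PRESENT_STATES = (
    MethylationState.NONE,
    MethylationState.HEMI_INTERNAL,
    MethylationState.FULL_INTERNAL,
    MethylationState.HEMI_EXTERNAL,
)
_ABSENT_STATES = (MethylationState.FULL_EXTERNAL, MethylationState.DOUBLE)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic experiment.

    Defaults mirror the targeted experimental design: nine primer
    combinations, four replicate individuals per variant, 10x amplicon
    coverage, amplicon sizes averaging ~200 bp inside the 50-500 bp
    detectable window, and a Roche-454-like substitution error rate.
    """

    seed: int = 0
    genome_length: int = 20_000
    target_gaattc_sites: int = 36
    target_ccgg_sites: int = 36
    n_changes_per_pair: int = 6
    n_shared: int = 3
    read_error_rate: float = 0.005
    coverage: int = 10
    replicates_per_variant: int = 4
    size_range: tuple[int, int] = (60, 340)
    #: background CCGG state distribution (unstated in real material;
    #: an arbitrary but plausible mix dominated by unmethylated sites)
    background_weights: tuple[tuple[str, float], ...] = (
        ("NONE", 0.60),
        ("FULL_INTERNAL", 0.25),
        ("FULL_EXTERNAL", 0.10),
        ("DOUBLE", 0.05),
    )

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1 kb")
        if not 0 <= self.n_shared <= self.n_changes_per_pair:
            raise ValueError("need 0 <= n_shared <= n_changes_per_pair")
        if not 0.0 <= self.read_error_rate <= 1.0:
            raise ValueError("read_error_rate must lie in [0, 1]")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")


@dataclass(frozen=True)
class CassetteRecord:
    """One planted amplicon cassette: its combo, coordinates, and size."""

    combo_id: str
    gaattc_pos: int
    ccgg_pos: int
    size_bp: int
    shared_id: Optional[str] = None

    @property
    def fragment_span(self) -> tuple[int, int]:
        # EcoRI cut G^AATTC at +1, CCGG cut C^CGG at +1
        return self.gaattc_pos + 1, self.ccgg_pos + 1


@dataclass(frozen=True)
class GenomeBuild:
    """A synthetic genome plus its planted structure and background
    methylome."""

    id: str
    sequence: str
    cassettes: tuple[CassetteRecord, ...]
    methylome: Methylome

    def cassette_at(self, ccgg_pos: int) -> CassetteRecord:
        for c in self.cassettes:
            if c.ccgg_pos == ccgg_pos:
                return c
        raise KeyError(ccgg_pos)


@dataclass(frozen=True)
class TruthRecord:
    """One planted methylation change and its expected band effects."""

    pair_id: int
    position: int
    old_state: MethylationState
    new_state: MethylationState
    shared: bool
    #: (combo_id, channel, size_bp, "gained"|"lost") per affected band
    expected_amplicons: tuple[tuple[str, str, int, str], ...]
    shared_id: Optional[str] = None


@dataclass(frozen=True)
class SyntheticExperiment:
    config: SimulationConfig
    combos: tuple[PrimerCombo, ...]
    genomes: Mapping[int, GenomeBuild]
    somaclone_methylomes: Mapping[int, Methylome]
    truth: tuple[TruthRecord, ...]

    def standard_methylome(self, pair_id: int) -> Methylome:
        return self.genomes[pair_id].methylome

    def spectra(
        self, pair_id: int, role: str, combos: Optional[Sequence[PrimerCombo]] = None
    ) -> list[AmpliconRecord]:
        """Predicted amplicons of one variant, all requested combos and
        both digestion channels."""
        build = self.genomes[pair_id]
        meth = (
            build.methylome if role == "standard" else self.somaclone_methylomes[pair_id]
        )
        out: list[AmpliconRecord] = []
        for combo in combos if combos is not None else self.combos:
            for channel in Channel:
                out.extend(
                    predicted_amplicons(
                        build.sequence, meth, combo, channel, genome_id=build.id
                    )
                )
        return out

    def sample_spectra(
        self, combos: Optional[Sequence[PrimerCombo]] = None
    ) -> dict[str, list[tuple[str, str, int]]]:
        """Per-replicate-sample band lists for the MSAP matrix stage:
        ``{pair}_{role}_{replicate}`` -> [(combo, channel, size), ...]."""
        out: dict[str, list[tuple[str, str, int]]] = {}
        for pair_id in sorted(self.genomes):
            for role in ("standard", "somaclone"):
                bands = [
                    (a.combo_id, a.channel.value, a.size_bp)
                    for a in self.spectra(pair_id, role, combos)
                ]
                for rep in range(1, self.config.replicates_per_variant + 1):
                    out[f"P{pair_id}_{role}_{rep}"] = list(bands)
        return out

    def amplicon_pools(
        self, combos: Optional[Sequence[PrimerCombo]] = None
    ) -> dict[str, list[str]]:
        """Pooled unique amplicon sequences per sequencing sample
        (Table-2 layout: 1 = pair-1 standard, 2 = pair-1 somaclone,
        3 = pair-2 standard, 4 = pair-2 somaclone)."""
        layout = {"1": (1, "standard"), "2": (1, "somaclone"),
                  "3": (2, "standard"), "4": (2, "somaclone")}
        pools: dict[str, list[str]] = {}
        for pool_no, (pair_id, role) in layout.items():
            seqs = sorted({a.sequence for a in self.spectra(pair_id, role, combos)})
            pools[pool_no] = seqs
        return pools

    def expected_shared_sequences(self) -> set[str]:
        """Amplicon sequences whose pooled presence differs between
        standard and somaclone in BOTH pairs (the planted consensual
        set, up to reverse complement)."""
        per_pair: list[set[str]] = []
        for pair_id in sorted(self.genomes):
            std = {a.sequence for a in self.spectra(pair_id, "standard")}
            som = {a.sequence for a in self.spectra(pair_id, "somaclone")}
            per_pair.append(std ^ som)
        shared = set.intersection(*per_pair) if per_pair else set()
        return shared


# ---------------------------------------------------------------------------
# genome assembly


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n > 0 else ""


def _clean_insert(combo: PrimerCombo, length: int, rng: np.random.Generator) -> str:
    """Random cassette insert whose full cassette string contains
    exactly the two flanking planted motifs and no interior one.

    Needed for shared cassettes, which are protected from scrubbing and
    must therefore be internally clean by construction.
    """
    for _ in range(200):
        insert = _random_seq(rng, length)
        cassette = (
            ECORI_MOTIF + combo.ecoRI_selective + insert + combo.hh_selective + CCGG_MOTIF
        )
        eco, ccgg = find_sites(cassette)
        if eco == [0] and ccgg == [len(cassette) - 4]:
            return insert
    raise RuntimeError("could not draw a motif-free cassette insert")


def _scrub(
    seq: list[str],
    planted_gaattc: set[int],
    planted_ccgg: set[int],
    cassette_ccgg: set[int],
    protected: set[int],
    rng: np.random.Generator,
) -> None:
    """Mutate bases until the genome contains no motif occurrence and no
    selective-matching context beyond the planted ones.

    Removed in place: unplanted GAATTC/CCGG occurrences; HpaII/MspI-side
    selective matches downstream of any CCGG (would create an HH-left
    amplifiable fragment) or upstream of a non-cassette CCGG; EcoRI-side
    selective matches upstream of any GAATTC or downstream of a
    non-cassette GAATTC.
    """
    e_sels = {c.ecoRI_selective for c in DEFAULT_COMBOS}
    h_sels = {c.hh_selective for c in DEFAULT_COMBOS}
    n = len(seq)
    # cassette GAATTC positions carry an intended (protected) selective
    # triplet right after the motif; bare ones do not
    cassette_gaattc = {p for p in planted_gaattc if (p + 6) in protected}

    def violations() -> list[tuple[int, int]]:
        s = "".join(seq)
        bad: list[tuple[int, int]] = []
        eco, ccgg = find_sites(s)
        for p in eco:
            if p not in planted_gaattc:
                bad.append((p, p + 6))
        for q in ccgg:
            if q not in planted_ccgg:
                bad.append((q, q + 4))
        for q in planted_ccgg:
            if q + 8 <= n and revcomp(s[q + 4 : q + 8]) in h_sels:
                bad.append((q + 4, q + 8))
            if q not in cassette_ccgg and q >= 4 and s[q - 4 : q] in h_sels:
                bad.append((q - 4, q))
        for p in planted_gaattc:
            if p >= 3 and revcomp(s[p - 3 : p]) in e_sels:
                bad.append((p - 3, p))
            if p not in cassette_gaattc and p + 9 <= n and s[p + 6 : p + 9] in e_sels:
                bad.append((p + 6, p + 9))
        return bad

    for _ in range(200):
        bad = violations()
        if not bad:
            return
        for lo, hi in bad:
            free = [i for i in range(lo, hi) if 0 <= i < n and i not in protected]
            if not free:
                raise RuntimeError("cannot scrub: violation window fully protected")
            i = free[len(free) // 2]
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = str(rng.choice(choices))
    raise RuntimeError("genome scrubbing did not converge")


def make_genome(
    config: SimulationConfig,
    *,
    genome_id: str = "g1",
    seed: Optional[int] = None,
    combos: Sequence[PrimerCombo] = DEFAULT_COMBOS,
    shared_cassettes: Sequence[tuple[str, str, str]] = (),
    rng: Optional[np.random.Generator] = None,
) -> GenomeBuild:
    """Build one synthetic cultivar genome.

    The genome alternates motif-free random spacers with amplicon
    cassettes (one controllable CCGG each) until the GAATTC/CCGG target
    counts are met; remaining targets are planted as bare motifs inside
    spacers.  `shared_cassettes` are (shared_id, combo_id, insert)
    triples planted verbatim — passing the same triples to two genomes
    plants an identical local sequence context in both.  Deterministic
    given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    combo_by_id = {c.id: c for c in combos}

    n_cassettes = min(config.target_gaattc_sites, config.target_ccgg_sites)
    if n_cassettes < 1:
        raise ValueError("need at least one cassette (site targets too small)")
    n_bare_gaattc = config.target_gaattc_sites - n_cassettes
    n_bare_ccgg = config.target_ccgg_sites - n_cassettes

    # one unique size per cassette (fragment length = 13 + insert
    # length); shared-cassette sizes are excluded so no band of a
    # genome ever comigrates with a planted shared band
    lo, hi = config.size_range
    own_count = n_cassettes - len(shared_cassettes)
    if own_count < 0:
        raise ValueError("more shared cassettes than cassette slots")
    shared_sizes = {len(ins) + 13 for _sid, _cid, ins in shared_cassettes}
    size_pool = np.array([s for s in range(lo, hi + 1) if s not in shared_sizes])
    if own_count > len(size_pool):
        raise ValueError("size_range too narrow for distinct cassette sizes")
    sizes = rng.choice(size_pool, size=own_count, replace=False)

    specs: list[tuple[Optional[str], str, str]] = []  # (shared_id, combo_id, insert)
    for shared_id, combo_id, insert in shared_cassettes:
        specs.append((shared_id, combo_id, insert))
    for k in range(own_count):
        combo = combos[int(rng.integers(len(combos)))]
        insert = _random_seq(rng, int(sizes[k]) - 13)
        specs.append((None, combo.id, insert))
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]

    cassette_seqs = []
    for shared_id, combo_id, insert in specs:
        combo = combo_by_id[combo_id]
        cassette_seqs.append(
            ECORI_MOTIF + combo.ecoRI_selective + insert + combo.hh_selective + CCGG_MOTIF
        )
    bare = [ECORI_MOTIF] * n_bare_gaattc + [CCGG_MOTIF] * n_bare_ccgg
    blocks = cassette_seqs + bare
    block_order = list(range(len(cassette_seqs))) + [-1] * len(bare)
    perm = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in perm]
    block_order = [block_order[i] for i in perm]

    content = sum(len(b) for b in blocks)
    n_gaps = len(blocks) + 1
    spacer_len = max(20, (config.genome_length - content) // n_gaps)
    if spacer_len < 12:
        raise ValueError("infeasible site density: spacers too short")

    parts: list[str] = []
    starts: list[int] = []
    pos = 0
    for b in blocks:
        sp = _random_seq(rng, spacer_len)
        parts.append(sp)
        pos += len(sp)
        starts.append(pos)
        parts.append(b)
        pos += len(b)
    parts.append(_random_seq(rng, spacer_len))
    seq = list("".join(parts))

    planted_gaattc: set[int] = set()
    planted_ccgg: set[int] = set()
    cassette_ccgg: set[int] = set()
    protected: set[int] = set()
    cassettes: list[CassetteRecord] = []
    for start, block, idx in zip(starts, blocks, block_order):
        if idx == -1:  # bare motif
            if block == ECORI_MOTIF:
                planted_gaattc.add(start)
            else:
                planted_ccgg.add(start)
            protected.update(range(start, start + len(block)))
            continue
        shared_id, combo_id, insert = specs[idx]
        g = start
        q = start + len(block) - 4
        planted_gaattc.add(g)
        planted_ccgg.add(q)
        cassette_ccgg.add(q)
        # motifs + selective extensions are immutable; the insert of an
        # own cassette may be mutated by scrubbing, but a shared
        # cassette must stay byte-identical across genomes, so its whole
        # span is protected (its insert is pre-sanitised)
        protected.update(range(g, g + 9))  # GAATTC + e_sel
        protected.update(range(q - 4, q + 4))  # h_sel + CCGG
        if shared_id is not None:
            protected.update(range(g, q + 4))
        cassettes.append(
            CassetteRecord(
                combo_id=combo_id,
                gaattc_pos=g,
                ccgg_pos=q,
                size_bp=(q + 1) - (g + 1),
                shared_id=shared_id,
            )
        )

    _scrub(seq, planted_gaattc, planted_ccgg, cassette_ccgg, protected, rng)
    sequence = "".join(seq)

    # background methylome over every planted CCGG site
    labels = [w[0] for w in config.background_weights]
    weights = np.array([w[1] for w in config.background_weights], dtype=float)
    weights = weights / weights.sum()
    states = {}
    for q in sorted(planted_ccgg):
        states[q] = MethylationState(labels[int(rng.choice(len(labels), p=weights))])
    build = GenomeBuild(
        id=genome_id,
        sequence=sequence,
        cassettes=tuple(sorted(cassettes, key=lambda c: c.gaattc_pos)),
        methylome=Methylome(states),
    )
    build.methylome.validate_against(sequence)
    return build


# ---------------------------------------------------------------------------
# somaclone derivation


def _presence(state: MethylationState) -> bool:
    return any(classify_cleavage(ch.enzyme, state) for ch in Channel)


def _band_effects(
    build: GenomeBuild,
    old_meth: Methylome,
    new_meth: Methylome,
    combos: Sequence[PrimerCombo],
) -> tuple[tuple[str, str, int, str], ...]:
    """Band-level differences (combo, channel, size, gained|lost) of the
    full predicted spectra, recomputed through the digestion engine."""
    effects = []
    for combo in combos:
        for channel in Channel:
            old = {
                a.size_bp
                for a in predicted_amplicons(build.sequence, old_meth, combo, channel)
            }
            new = {
                a.size_bp
                for a in predicted_amplicons(build.sequence, new_meth, combo, channel)
            }
            for size in sorted(new - old):
                effects.append((combo.id, channel.value, size, "gained"))
            for size in sorted(old - new):
                effects.append((combo.id, channel.value, size, "lost"))
    return tuple(effects)


def derive_somaclone(
    build: GenomeBuild,
    methylome: Methylome,
    config: SimulationConfig,
    *,
    pair_id: int = 1,
    rng: Optional[np.random.Generator] = None,
    sites: Optional[Sequence[tuple[int, MethylationState]]] = None,
    combos: Sequence[PrimerCombo] = DEFAULT_COMBOS,
) -> tuple[Methylome, list[TruthRecord]]:
    """Derive a somaclone methylome by flipping planted CCGG states.

    Flips are chosen at cassette sites and always cross the pooled
    presence/absence divide (a band appears or disappears in at least
    one digestion channel, and the amplicon sequence enters or leaves
    the pooled read space).  `sites` may pin (position, new_state)
    choices explicitly — used to replay the same flip on a shared
    cassette in the second pair.
    """
    rng = rng or np.random.default_rng(config.seed)
    chosen: list[tuple[int, MethylationState]]
    if sites is not None:
        chosen = [(int(p), MethylationState(s)) for p, s in sites]
    else:
        positions = [c.ccgg_pos for c in build.cassettes]
        k = config.n_changes_per_pair
        if k > len(positions):
            raise ValueError("not enough cassette CCGG sites for the requested flips")
        idx = rng.choice(len(positions), size=k, replace=False)
        chosen = []
        for i in idx:
            pos = positions[int(i)]
            old = methylome.state_at(pos)
            pool = _ABSENT_STATES if _presence(old) else (_PRESENT_STATES[0],)
            new = MethylationState(pool[int(rng.integers(len(pool)))])
            chosen.append((pos, new))

    som = dict(methylome.states)
    records: list[TruthRecord] = []
    for pos, new_state in chosen:
        old_state = methylome.state_at(pos)
        if old_state == new_state:
            raise ValueError(f"site {pos}: flip must change the state")
        single = Methylome({**methylome.states, pos: new_state})
        effects = _band_effects(build, methylome, single, combos)
        if not effects:
            raise ValueError(f"site {pos}: flip {old_state}->{new_state} changes no spectrum")
        som[pos] = new_state
        cassette = build.cassette_at(pos)
        records.append(
            TruthRecord(
                pair_id=pair_id,
                position=pos,
                old_state=old_state,
                new_state=new_state,
                shared=cassette.shared_id is not None,
                expected_amplicons=effects,
                shared_id=cassette.shared_id,
            )
        )
    return Methylome(som), records


# ---------------------------------------------------------------------------
# read simulation


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_reads(
    pools: Mapping[str, Sequence[str]],
    config: SimulationConfig,
    *,
    mid_table: Mapping[str, str] = DEFAULT_MID_TABLE,
    rng: Optional[np.random.Generator] = None,
    quality: int = 30,
) -> list[SequencedRead]:
    """Simulate pooled, barcoded amplicon reads.

    For every amplicon sequence in every pool, `coverage` full-length
    reads are emitted in a random orientation, substitution errors are
    applied at the configured per-base rate (over the whole read,
    barcode included), the pool's MID barcode is prepended, and a
    constant Phred quality is assigned.  Deterministic given the RNG.
    """
    rng = rng or np.random.default_rng(config.seed)
    reads: list[SequencedRead] = []
    for pool_no in sorted(pools):
        barcode = mid_table[pool_no]
        for j, amplicon in enumerate(sorted(pools[pool_no])):
            for k in range(config.coverage):
                insert = amplicon if rng.random() < 0.5 else revcomp(amplicon)
                bases = _mutate(barcode + insert, config.read_error_rate, rng)
                reads.append(
                    SequencedRead(
                        id=f"pool{pool_no}_amp{j}_read{k}",
                        bases=bases,
                        qualities=tuple([quality] * len(bases)),
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# whole-experiment builder


def simulate_experiment(
    config: SimulationConfig,
    combos: Sequence[PrimerCombo] = DEFAULT_COMBOS,
) -> SyntheticExperiment:
    """Generate the full two-pair synthetic study.

    Two unrelated cultivar genomes are built; `n_shared` cassettes are
    planted verbatim in both.  Each pair's somaclone flips
    `n_changes_per_pair` cassette states, and for shared cassettes the
    identical flip (same old state, same new state, identical cassette
    sequence) is applied in both pairs, making those amplicon changes
    recoverable as the consensual differential set.
    """
    rng = np.random.default_rng(config.seed)
    combo_list = list(combos)

    lo, hi = config.size_range
    shared_specs: list[tuple[str, str, str]] = []
    shared_flips: dict[str, tuple[MethylationState, MethylationState]] = {}
    used_sizes = rng.choice(
        np.arange(lo, hi + 1), size=config.n_shared, replace=False
    ) if config.n_shared else np.array([], dtype=int)
    for i in range(config.n_shared):
        combo = combo_list[int(rng.integers(len(combo_list)))]
        insert = _clean_insert(combo, int(used_sizes[i]) - 13, rng)
        sid = f"shared{i + 1}"
        shared_specs.append((sid, combo.id, insert))
        if rng.random() < 0.5:  # band lost in the somaclones
            old = MethylationState.NONE
            new = MethylationState(_ABSENT_STATES[int(rng.integers(2))])
        else:  # band gained in the somaclones
            old = MethylationState(_ABSENT_STATES[int(rng.integers(2))])
            new = MethylationState.NONE
        shared_flips[sid] = (old, new)

    genomes: dict[int, GenomeBuild] = {}
    somaclones: dict[int, Methylome] = {}
    truth: list[TruthRecord] = []
    for pair_id in (1, 2):
        build = make_genome(
            config,
            genome_id=f"cultivar{pair_id}",
            combos=combo_list,
            shared_cassettes=shared_specs,
            rng=rng,
        )
        # pin shared-cassette background states to the shared flip's old state
        states = dict(build.methylome.states)
        for c in build.cassettes:
            if c.shared_id is not None:
                states[c.ccgg_pos] = shared_flips[c.shared_id][0]
        build = GenomeBuild(
            id=build.id,
            sequence=build.sequence,
            cassettes=build.cassettes,
            methylome=Methylome(states),
        )
        genomes[pair_id] = build

        pinned = [
            (c.ccgg_pos, shared_flips[c.shared_id][1])
            for c in build.cassettes
            if c.shared_id is not None
        ]
        own_candidates = [c.ccgg_pos for c in build.cassettes if c.shared_id is None]
        n_own = config.n_changes_per_pair - config.n_shared
        idx = rng.choice(len(own_candidates), size=n_own, replace=False)
        own = []
        for i in idx:
            pos = own_candidates[int(i)]
            old = build.methylome.state_at(pos)
            pool = _ABSENT_STATES if _presence(old) else (MethylationState.NONE,)
            own.append((pos, MethylationState(pool[int(rng.integers(len(pool)))])))
        som, records = derive_somaclone(
            build,
            build.methylome,
            config,
            pair_id=pair_id,
            sites=pinned + own,
            combos=combo_list,
        )
        somaclones[pair_id] = som
        truth.extend(records)

    return SyntheticExperiment(
        config=config,
        combos=tuple(combo_list),
        genomes=genomes,
        somaclone_methylomes=somaclones,
        truth=tuple(truth),
    )
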