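"""Readers and writers for the pipeline's plain-text formats.

FASTA/FASTQ go through Biopython; tabular artifacts (methylomes, band
matrices, spectra, similarity tables, polymorphism accounts, truth sets,
differential reports) are TSV/CSV with header rows; trees are Newick.
All formats round-trip without information loss.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .contigs import Contig, SequencedRead
from .digest import MethylationState, Methylome
from .landscape import BandMatrix

FASTA_WIDTH = 80

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_methylome",
    "read_methylome",
    "write_band_matrix",
    "read_band_matrix",
    "write_spectra",
    "read_spectra",
    "write_contigs_fasta",
    "read_contigs_fasta",
]


def _records(sequences: Mapping[str, str]) -> list[SeqRecord]:
    return [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(_records(sequences))


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> None:
    """Sanger FASTQ (Phred+33)."""
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_fastq(path: str | Path) -> list[SequencedRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            SequencedRead(
                id=rec.id,
                bases=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_methylome(
    methylomes: Mapping[str, Methylome], path: str | Path
) -> None:
    """TSV: genome_id, position (0-based first C of CCGG), state."""
    rows = [
        {"genome_id": gid, "position": pos, "state": state.value}
        for gid, meth in methylomes.items()
        for pos, state in sorted(meth.states.items())
    ]
    pd.DataFrame(rows, columns=["genome_id", "position", "state"]).to_csv(
        path, sep="\t", index=False
    )


def read_methylome(path: str | Path) -> dict[str, Methylome]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, Methylome] = {}
    for gid, grp in df.groupby("genome_id", sort=True):
        out[str(gid)] = Methylome(
            {int(r.position): MethylationState(r.state) for r in grp.itertuples()}
        )
    return out


def write_band_matrix(matrix: BandMatrix, path: str | Path) -> None:
    """Samples x bands TSV; columns are ``combo:channel:bin`` keys."""
    matrix.data.to_csv(path, sep="\t", index_label="sample")


def read_band_matrix(path: str | Path) -> BandMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return BandMatrix(df.astype(int))


def write_spectra(
    spectra: Mapping[str, Sequence[tuple[str, str, int]]], path: str | Path
) -> None:
    """CSV: sample, combo, channel, size_bp."""
    rows = [
        {"sample": s, "combo": c, "channel": ch, "size_bp": size}
        for s, bands in spectra.items()
        for c, ch, size in sorted(bands)
    ]
    pd.DataFrame(rows, columns=["sample", "combo", "channel", "size_bp"]).to_csv(
        path, index=False
    )


def read_spectra(path: str | Path) -> dict[str, list[tuple[str, str, int]]]:
    df = pd.read_csv(path)
    out: dict[str, list[tuple[str, str, int]]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.sample), []).append(
            (str(r.combo), str(r.channel), int(r.size_bp))
        )
    return out


def write_contigs_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    """Per-pool contig FASTA; headers ``id|reads=K|pool=P``."""
    seqs = {f"{c.id}|reads={c.read_count}|pool={c.pool}": c.consensus for c in contigs}
    write_fasta(seqs, path)


def read_contigs_fasta(path: str | Path) -> list[Contig]:
    out = []
    for name, seq in read_fasta(path).items():
        cid, reads, pool = name.split("|")
        out.append(
            Contig(
                id=cid,
                consensus=seq,
                read_count=int(reads.removeprefix("reads=")),
                pool=pool.removeprefix("pool="),
            )
        )
    return out
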