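"""DNA-methylation-landscape comparison from MSAP band spectra.

Per-sample band spectra (combo, channel, size) are binned into a binary
presence/absence matrix; pairwise epigenetic similarity is the Nei-Li /
Dice band-sharing coefficient S = 2a/(2a+b+c) (joint absences carry no
information and are ignored); samples are clustered with UPGMA; and the
gained/lost polymorphic-band bookkeeping across cultivar/somaclone pairs
is tabulated in the style of an MSAP polymorphism table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .digest import Channel

__all__ = [
    "BandMatrix",
    "SimilarityResult",
    "Dendrogram",
    "PolymorphismAccount",
    "build_band_matrix",
    "dice_similarity",
    "polymorphic_percent",
    "similarity_matrix",
    "upgma_tree",
    "polymorphism_accounting",
    "round_half_up",
]

BandKey = Tuple[str, str, int]  # (combo_id, channel, size bin)


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at `ndigits` decimals (reported values
    use this, not banker's rounding).

    A 12-decimal guard rounding is applied first so that a decimal
    half-point reached through float arithmetic (e.g. a mean of
    4-decimal similarities landing on ...5) still rounds upward.
    """
    q = Decimal(1).scaleb(-ndigits)
    guarded = Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-12), rounding=ROUND_HALF_UP)
    return float(guarded.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BandMatrix:
    """Samples x bands binary presence/absence matrix.

    ``data`` is a pandas DataFrame with sample labels as the index and
    ``combo:channel:bin`` strings as columns; cells are 0/1 ints.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample labels")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate band keys")
        if len(self.data.index) == 0:
            raise ValueError("band matrix needs at least one sample")
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("band matrix cells must be strictly 0/1")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def bands(self) -> list[BandKey]:
        return [self.parse_band_key(c) for c in self.data.columns]

    @staticmethod
    def band_key_str(combo_id: str, channel: str, size_bin: int) -> str:
        return f"{combo_id}:{channel}:{size_bin}"

    @staticmethod
    def parse_band_key(key: str) -> BandKey:
        combo, channel, size_bin = key.rsplit(":", 2)
        return combo, channel, int(size_bin)

    def row(self, sample: str) -> np.ndarray:
        return self.data.loc[sample].to_numpy()


@dataclass(frozen=True)
class SimilarityResult:
    """Nei-Li/Dice band-sharing similarity between two samples."""

    a: int  # bands present in both
    b: int  # bands unique to the first sample
    c: int  # bands unique to the second
    S: float

    @property
    def distance(self) -> float:
        return 1.0 - self.S


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric UPGMA tree over sample labels.

    ``newick`` carries branch lengths (half merge-height differences);
    ``heights`` maps each internal merge to its ultrametric height.
    """

    newick: str
    heights: tuple[float, ...]
    leaves: tuple[str, ...]


def build_band_matrix(
    spectra: Mapping[str, Iterable[tuple]],
    bin_width: int = 1,
) -> BandMatrix:
    """Bin per-sample spectra into a binary band matrix.

    `spectra` maps sample label -> iterable of (combo_id, channel,
    size_bp).  Sizes are assigned to integer bins of width `bin_width`
    (floor division); a cell is 1 iff the sample shows at least one band
    in that bin for that combo/channel.  MSP- and HPA-channel bands are
    kept as separate columns of the one matrix, i.e. the two digestion
    channels are combined per sample.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    samples = list(spectra)
    if len(samples) != len(set(samples)):
        raise ValueError("duplicate sample labels")
    cells: dict[str, set[str]] = {s: set() for s in samples}
    all_keys: dict[str, BandKey] = {}
    for sample, bands in spectra.items():
        for combo_id, channel, size_bp in bands:
            if size_bp <= 0:
                raise ValueError(f"non-positive band size {size_bp!r}")
            key_t = (str(combo_id), Channel(channel).value, int(size_bp // bin_width))
            key = BandMatrix.band_key_str(*key_t)
            all_keys[key] = key_t
            cells[sample].add(key)
    columns = sorted(all_keys, key=lambda k: all_keys[k])
    data = pd.DataFrame(
        [[1 if k in cells[s] else 0 for k in columns] for s in samples],
        index=samples,
        columns=columns,
        dtype=int,
    )
    return BandMatrix(data)


def dice_similarity(row_x: Sequence[int], row_y: Sequence[int]) -> SimilarityResult:
    """Nei-Li/Dice similarity S = 2a/(2a+b+c) between two binary rows."""
    x = np.asarray(row_x)
    y = np.asarray(row_y)
    if x.shape != y.shape:
        raise ValueError("rows must have equal length")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("rows must be binary")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    denom = 2 * a + b + c
    if denom == 0:
        raise ValueError("similarity undefined: no band present in either sample")
    return SimilarityResult(a=a, b=b, c=c, S=2 * a / denom)


def polymorphic_percent(S: float) -> float:
    """Percent of polymorphic bands implied by a Dice similarity S.

    With a shared and b+c unique bands, S = 2a/(2a+b+c) and the
    polymorphic fraction is (b+c)/(a+b+c); eliminating the counts gives
    p = 100 * 2(1-S)/(2-S).  Strictly decreasing from p(0)=100 to
    p(1)=0.
    """
    if not 0.0 <= S <= 1.0:
        raise ValueError("S must lie in [0, 1]")
    return 100.0 * 2.0 * (1.0 - S) / (2.0 - S)


def similarity_matrix(matrix: BandMatrix) -> pd.DataFrame:
    """Symmetric pairwise Dice-similarity table with unit diagonal."""
    samples = matrix.samples
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    out = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, si in enumerate(samples):
        for sj in samples[i + 1 :]:
            s = dice_similarity(matrix.row(si), matrix.row(sj)).S
            out.loc[si, sj] = out.loc[sj, si] = s
    return out


def upgma_tree(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance matrix.

    Arithmetic-mean linkage; at each step the pair at minimal distance
    is merged, ties broken by the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf).  Leaf
    branch lengths are half the merge height; internal branch lengths
    are half-height differences, so the tree is ultrametric.
    """
    labels = list(distances.index)
    d = distances.to_numpy(dtype=float)
    if list(distances.columns) != labels:
        raise ValueError("distance matrix index/columns must agree")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any() or not np.allclose(np.diag(d), 0):
        raise ValueError("distances must be non-negative with zero diagonal")

    # cluster state: label -> (newick, height, size, members)
    clusters: dict[str, tuple[str, float, int]] = {
        lab: (lab, 0.0, 1) for lab in labels
    }
    dist: dict[frozenset, float] = {
        frozenset((labels[i], labels[j])): d[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    heights: list[float] = []
    while len(clusters) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0]))))
        (pair, dmin) = best
        x, y = sorted(pair)
        h = dmin / 2.0
        nwx, hx, sx = clusters.pop(x)
        nwy, hy, sy = clusters.pop(y)
        newick = f"({nwx}:{h - hx:.10g},{nwy}:{h - hy:.10g})"
        heights.append(h)
        del dist[pair]
        merged = x  # label by smallest leaf
        for other in list(clusters):
            dxz = dist.pop(frozenset((x, other)))
            dyz = dist.pop(frozenset((y, other)))
            dist[frozenset((merged, other))] = (sx * dxz + sy * dyz) / (sx + sy)
        clusters[merged] = (newick, h, sx + sy)
    (root_newick, _, _) = next(iter(clusters.values()))
    return Dendrogram(
        newick=root_newick + ";",
        heights=tuple(heights),
        leaves=tuple(sorted(labels)),
    )


@dataclass(frozen=True)
class PolymorphismAccount:
    """Gained/lost polymorphic-band counts per (combo, channel).

    ``table`` columns: one_gained/one_lost (bands polymorphic within
    exactly one cultivar pair), both_gained/both_lost/both_mixed (bands
    polymorphic within both pairs; mixed = opposite direction in the two
    pairs), and total.  "Gained" means present in every somaclone
    replicate and absent from every standard replicate of the pair
    (unanimity consensus); "lost" is the reverse.
    """

    table: pd.DataFrame
    band_scope: Mapping[str, str] = field(default_factory=dict)

    _COLS = ("one_gained", "one_lost", "both_gained", "both_lost", "both_mixed", "total")

    def total_within_both(self) -> int:
        return int(
            self.table[["both_gained", "both_lost", "both_mixed"]].to_numpy().sum()
        )

    def combos_with_within_both(self) -> list[str]:
        t = self.table[["both_gained", "both_lost", "both_mixed"]].sum(axis=1)
        return sorted({combo for (combo, _ch), v in t.items() if v > 0})

    def combo_channel_totals(self) -> pd.Series:
        return self.table["total"]


def polymorphism_accounting(
    matrix: BandMatrix,
    groups: Mapping[str, tuple[str, str]],
) -> PolymorphismAccount:
    """Tabulate gained/lost bands per combo/channel across pairs.

    `groups` maps each sample label to ``(pair_id, role)`` with role
    "standard" or "somaclone".  A band is *gained* in a pair when all of
    that pair's somaclone samples carry it and none of its standard
    samples do, *lost* in the reverse case; replicate-inconsistent bands
    are ignored.  A band gained-or-lost in both pairs is scoped
    WITHIN_BOTH_PAIRS, in exactly one pair WITHIN_ONE_PAIR.
    """
    for s in groups:
        if s not in matrix.data.index:
            raise ValueError(f"unknown sample {s!r} in groups")
    pairs: dict[str, dict[str, list[str]]] = {}
    for sample, (pair_id, role) in groups.items():
        if role not in ("standard", "somaclone"):
            raise ValueError(f"role must be standard/somaclone, got {role!r}")
        pairs.setdefault(pair_id, {}).setdefault(role, []).append(sample)
    for pair_id, roles in pairs.items():
        if not roles.get("standard") or not roles.get("somaclone"):
            raise ValueError(f"pair {pair_id!r} needs >=1 standard and >=1 somaclone")

    pair_ids = sorted(pairs)
    combos_channels = sorted({(c, ch) for (c, ch, _b) in matrix.bands})
    table = pd.DataFrame(
        0,
        index=pd.MultiIndex.from_tuples(combos_channels, names=["combo", "channel"]),
        columns=list(PolymorphismAccount._COLS),
    )
    band_scope: dict[str, str] = {}
    for key in matrix.data.columns:
        combo, channel, _b = BandMatrix.parse_band_key(key)
        col = matrix.data[key]
        directions: dict[str, str] = {}
        for pair_id in pair_ids:
            std = col[pairs[pair_id]["standard"]]
            som = col[pairs[pair_id]["somaclone"]]
            if (som == 1).all() and (std == 0).all():
                directions[pair_id] = "gained"
            elif (som == 0).all() and (std == 1).all():
                directions[pair_id] = "lost"
        if not directions:
            continue
        idx = (combo, channel)
        if len(directions) == len(pair_ids) and len(pair_ids) > 1:
            band_scope[key] = "WITHIN_BOTH_PAIRS"
            dirs = set(directions.values())
            if dirs == {"gained"}:
                table.loc[idx, "both_gained"] += 1
            elif dirs == {"lost"}:
                table.loc[idx, "both_lost"] += 1
            else:
                table.loc[idx, "both_mixed"] += 1
        else:
            band_scope[key] = "WITHIN_ONE_PAIR"
            direction = next(iter(directions.values()))
            table.loc[idx, f"one_{direction}"] += 1
    table["total"] = table[list(PolymorphismAccount._COLS[:-1])].sum(axis=1)
    return PolymorphismAccount(table=table, band_scope=band_scope)
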