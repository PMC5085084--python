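"""Sequencing-capacity planning and primer-combination selection.

Capacity arithmetic for pooled deep amplicon sequencing of MSAP
products: total nucleotides = mean amplicon length x amplicons per
primer combination x number of pooled samples x desired coverage x
number of combinations, checked against the sequencer's per-run
capacity.  Combination selection prioritises primer combinations whose
polymorphic amplicons recur in both cultivar/somaclone pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .digest import DEFAULT_COMBOS
from .landscape import PolymorphismAccount

__all__ = [
    "CapacityPlan",
    "capacity_estimate",
    "select_primer_combinations",
    "average_amplicons_per_combination",
]

_ROMAN_ORDER = {c.id: i for i, c in enumerate(DEFAULT_COMBOS)}


def _label_key(label: str):
    """Combo ordering: the canonical I..IX series first, others after,
    lexicographically."""
    return (0, _ROMAN_ORDER[label]) if label in _ROMAN_ORDER else (1, label)

#: per-run capacity of a Roche 454 GS Junior, nt
DEFAULT_DEVICE_CAPACITY = 35_000_000


@dataclass(frozen=True)
class CapacityPlan:
    mean_len: float
    amplicons_per_combo: float
    n_samples: float
    coverage: float
    n_combos: float
    total_nt: float
    device_capacity: float
    utilization: float

    def report(self) -> dict:
        return {
            "mean_amplicon_length_bp": self.mean_len,
            "amplicons_per_combination": self.amplicons_per_combo,
            "n_samples": self.n_samples,
            "coverage": self.coverage,
            "n_combinations": self.n_combos,
            "total_nt": self.total_nt,
            "device_capacity_nt": self.device_capacity,
            "utilization": self.utilization,
        }


def capacity_estimate(
    mean_len: float,
    amplicons_per_combo: float,
    n_samples: float,
    coverage: float = 1,
    n_combos: float = 1,
    device_capacity: float = DEFAULT_DEVICE_CAPACITY,
) -> CapacityPlan:
    """Required sequencing capacity in nucleotides.

    total_nt = mean_len * amplicons_per_combo * n_samples * coverage *
    n_combos; `utilization` is total_nt over the device capacity.
    E.g. 200 bp x 300 amplicons x 4 samples at 1x = 240,000 nt; at 10x
    with 6 combinations = 14,400,000 nt.
    """
    args = (mean_len, amplicons_per_combo, n_samples, coverage, n_combos)
    if any(a < 0 for a in args) or device_capacity < 0:
        raise ValueError("capacity factors must be non-negative")
    total = mean_len * amplicons_per_combo * n_samples * coverage * n_combos
    util = total / device_capacity if device_capacity > 0 else float("nan")
    return CapacityPlan(*args, total_nt=total, device_capacity=device_capacity, utilization=util)


def select_primer_combinations(
    account: PolymorphismAccount,
    max_combos: int,
    *,
    rank_channel: str = "HPA",
) -> list[str]:
    """Choose primer combinations to pool for amplicon sequencing.

    Every combination with at least one band polymorphic within both
    cultivar pairs is mandatory (those bands are the candidates for
    changes that recur under in vitro cultivation).  Remaining slots are
    filled by descending total polymorphic-band count in `rank_channel`
    (HpaII by default — the methylation-sensitive digestion that yields
    the richer polymorphism readout), ties broken by combination label
    order.  Returns labels in label order.
    """
    mandatory = account.combos_with_within_both()
    if max_combos < len(mandatory):
        raise ValueError(
            f"max_combos={max_combos} is smaller than the {len(mandatory)} "
            f"mandatory combinations with polymorphisms in both pairs: {mandatory}"
        )
    totals = account.combo_channel_totals()
    all_combos = sorted({combo for (combo, _ch) in totals.index}, key=_label_key)

    def rank_total(combo: str) -> int:
        key = (combo, rank_channel)
        return int(totals[key]) if key in totals.index else 0

    selected = set(mandatory)
    fillers = [c for c in all_combos if c not in selected]
    fillers.sort(key=lambda c: (-rank_total(c), _label_key(c)))
    for c in fillers[: max_combos - len(selected)]:
        selected.add(c)
    return sorted(selected, key=_label_key)


def average_amplicons_per_combination(total_amplicons: int, n_combos: int) -> int:
    """Report-style mean amplicon yield per primer combination, rounded
    to the nearest whole amplicon (e.g. 2081 over 9 combinations ~ 231)."""
    if n_combos <= 0:
        raise ValueError("n_combos must be positive")
    from .landscape import round_half_up

    return int(round_half_up(total_amplicons / n_combos, 0))
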