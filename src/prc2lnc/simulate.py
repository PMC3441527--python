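"""Synthetic two-class lncRNA-like sequence sets with planted signal.

The generator emulates the statistical structure the classifier exploits:
the positive (PRC2-binding-like) class is AT-enriched, carries planted tandem
repeat blocks (hence lower Lempel–Ziv complexity — tandem duplication is
provably compressive under the LZ76 parse) and optionally planted PWM motif
instances; the negative class is compositionally balanced with no planted
structure.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import PWM
from .seqio import NEGATIVE, POSITIVE, SequenceRecord, SequenceSet

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic two-class draw.

    ``at_fraction_*`` is the expected A+T fraction per class (A and T equal,
    C and G equal).  ``repeat_rate_pos`` is the expected number of planted
    tandem-repeat blocks per kb in positives; each block is a unit of
    ``repeat_unit_range`` nt repeated ``repeat_copies_range`` times.  A PWM
    plus ``motif_instances`` plants that many sampled motif occurrences in
    every positive sequence.
    """

    n_pos: int = 60
    n_neg: int = 60
    length_range: tuple[int, int] = (300, 2000)
    at_fraction_pos: float = 0.62
    at_fraction_neg: float = 0.50
    repeat_rate_pos: float = 1.0
    repeat_unit_range: tuple[int, int] = (8, 20)
    repeat_copies_range: tuple[int, int] = (3, 6)
    motif: PWM | None = None
    motif_instances: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("need at least 2 sequences per class")
        lo, hi = self.length_range
        if lo <= 100 or hi < lo:
            raise ValueError("length_range minimum must be > 100 nt")
        for f in (self.at_fraction_pos, self.at_fraction_neg):
            if not 0.0 < f < 1.0:
                raise ValueError("AT fractions must be in (0, 1)")
        if self.repeat_rate_pos < 0:
            raise ValueError("repeat_rate_pos must be >= 0")
        if self.motif is not None and self.motif.width > lo:
            raise ValueError("motif wider than the minimum sequence length")
        if self.motif is None and self.motif_instances:
            raise ValueError("motif_instances set without a motif")


def _iid_bases(rng: np.random.Generator, length: int, at_fraction: float) -> np.ndarray:
    p = np.array([at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2])
    return rng.choice(4, size=length, p=p)


def _place_blocks(
    rng: np.random.Generator, length: int, block_lengths: list[int], max_tries: int = 200
) -> list[int]:
    """Uniform non-overlapping start positions for blocks (skip on failure)."""
    occupied: list[tuple[int, int]] = []
    starts: list[int] = []
    for bl in block_lengths:
        if bl > length:
            continue
        for _ in range(max_tries):
            s = int(rng.integers(0, length - bl + 1))
            if all(s + bl <= a or s >= b for a, b in occupied):
                occupied.append((s, s + bl))
                starts.append(s)
                break
    return starts


def _sample_motif_instance(rng: np.random.Generator, pwm: PWM) -> np.ndarray:
    probs = np.exp(pwm.log_probabilities())
    return np.array([rng.choice(4, p=probs[:, j] / probs[:, j].sum()) for j in range(pwm.width)])


def generate(config: SyntheticConfig) -> SequenceSet:
    """Draw a labeled synthetic sequence set under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    lo, hi = config.length_range

    for i in range(config.n_pos):
        length = int(rng.integers(lo, hi + 1))
        codes = _iid_bases(rng, length, config.at_fraction_pos)
        # tandem repeat blocks
        n_blocks = rng.poisson(config.repeat_rate_pos * length / 1000.0)
        specs = []
        for _ in range(n_blocks):
            unit_len = int(rng.integers(*config.repeat_unit_range, endpoint=True))
            copies = int(rng.integers(*config.repeat_copies_range, endpoint=True))
            specs.append((unit_len, copies))
        starts = _place_blocks(rng, length, [u * c for u, c in specs])
        for (unit_len, copies), start in zip(specs, starts):
            unit = _iid_bases(rng, unit_len, config.at_fraction_pos)
            block = np.tile(unit, copies)
            codes[start : start + len(block)] = block
        # motif instances
        if config.motif is not None and config.motif_instances > 0:
            inst = [
                _sample_motif_instance(rng, config.motif)
                for _ in range(config.motif_instances)
            ]
            for start, ins in zip(
                _place_blocks(rng, length, [len(x) for x in inst]), inst
            ):
                codes[start : start + len(ins)] = ins
        records.append(
            SequenceRecord(f"pos_{i:04d}", "".join(_BASES[codes]), POSITIVE)
        )

    for i in range(config.n_neg):
        length = int(rng.integers(lo, hi + 1))
        codes = _iid_bases(rng, length, config.at_fraction_neg)
        records.append(
            SequenceRecord(f"neg_{i:04d}", "".join(_BASES[codes]), NEGATIVE)
        )

    return SequenceSet(records, name=f"synthetic_seed{config.seed}")


def truth_table(config: SyntheticConfig) -> dict:
    """Manifest of the signal planted by :func:`generate`.

    Recovery tests compare pipeline output against this: which k-word classes
    are expected enriched where, whether complexity should be depressed in
    positives, and which PWM feature is a true positive.
    """
    signals: list[dict] = []
    if config.at_fraction_pos > config.at_fraction_neg:
        signals.append(
            {"kind": "kmer_class", "iupac_class": "W", "enriched_class": POSITIVE}
        )
    elif config.at_fraction_pos < config.at_fraction_neg:
        signals.append(
            {"kind": "kmer_class", "iupac_class": "S", "enriched_class": POSITIVE}
        )
    if config.repeat_rate_pos > 0:
        signals.append(
            {"kind": "complexity", "feature": "kc", "lower_class": POSITIVE}
        )
    if config.motif is not None and config.motif_instances > 0:
        signals.append(
            {
                "kind": "motif",
                "feature": f"pwm:{config.motif.name}",
                "enriched_class": POSITIVE,
            }
        )
    return {"seed": config.seed, "signals": signals}


def write_truth_table(config: SyntheticConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_table(config), fh, indent=1)
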