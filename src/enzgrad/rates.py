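"""Parsing and normalizing site-specific evolutionary rates.

Rates arrive either in Rate4Site output format ('#'-prefixed header lines,
then position / amino acid / score columns) or as a plain two-column
``position<TAB>rate`` table.  Raw scores are rescaled so the per-protein
mean is exactly 1; the normalized rate K is dimensionless, K < 1 meaning
slower (more conserved) than the protein average.

Rates are mapped to structure residues strictly by order: the i-th rate
belongs to the i-th residue of the selected chain(s).  A length mismatch is
a hard error rather than a silent truncation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import NormalizationError, RateFormatError

logger = logging.getLogger(__name__)


@dataclass
class RateVector:
    """Raw and normalized site-specific rates for one protein."""

    protein_id: str
    raw: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        if self.raw.shape != self.K.shape:
            raise ValueError("raw and K must have the same length")
        if not np.all(np.isfinite(self.K)):
            raise ValueError("non-finite normalized rates")

    def __len__(self) -> int:
        return len(self.K)


def parse_rates(text: str, format: str = "two_column") -> np.ndarray:
    """Parse raw rate scores; positions must be consecutive from 1.

    ``rate4site`` format: comment/header lines begin with '#'; data lines
    carry POS, SEQ (one-letter amino acid), SCORE as the first three
    whitespace-separated fields.  ``two_column``: POS and RATE.
    """
    if format not in ("rate4site", "two_column"):
        raise ValueError(f"unknown rate format {format!r}")
    if not text.strip():
        raise RateFormatError("empty rate file")
    positions: list[int] = []
    scores: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        try:
            if format == "rate4site":
                if len(fields) < 3:
                    raise ValueError("expected POS SEQ SCORE")
                pos, score = int(fields[0]), float(fields[2])
            else:
                pos, score = int(fields[0]), float(fields[1])
        except (ValueError, IndexError) as exc:
            raise RateFormatError(f"unparseable rate line {lineno}: {line!r}") from exc
        positions.append(pos)
        scores.append(score)
    if not positions:
        raise RateFormatError("no data lines in rate file")
    expected = list(range(1, len(positions) + 1))
    if positions != expected:
        raise RateFormatError(
            f"positions must be consecutive from 1; got gaps or reordering "
            f"(first mismatch near position {next(p for p, e in zip(positions, expected) if p != e)})"
        )
    return np.asarray(scores, dtype=float)


def normalize_rates(raw, protein_id: str = "protein") -> RateVector:
    """Scale raw rates so their mean is exactly 1 (K = raw / mean(raw)).

    Idempotent and scale-invariant; a zero mean cannot be normalized.
    Negative raw scores (possible under some estimators) are accepted with
    a warning.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise NormalizationError("cannot normalize an empty rate vector")
    if not np.all(np.isfinite(raw)):
        raise NormalizationError("non-finite raw rates")
    mean = raw.mean()
    if mean == 0.0:
        raise NormalizationError("raw rates have zero mean")
    if np.any(raw < 0):
        logger.warning("%d negative raw rates accepted", int(np.sum(raw < 0)))
    return RateVector(protein_id=protein_id, raw=raw, K=raw / mean)
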