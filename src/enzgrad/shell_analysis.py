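"""Distance shells around functional sites and rate summaries over them.

Residues are organized into concentric 5 A shells by their distance d to the
nearest catalytic (or interface) residue: shell 0 spans [0, 2.5] and each
shell k >= 1 spans (5k - 2.5, 5k + 2.5].  5 A is roughly the minimum
separation of two side-chain centers, so shell 1 holds residues in direct
contact with the functional site, and the outer boundary of shell 5 sits at
27.5 A.  The convention is left-open/right-closed so that a residue at
exactly 27.5 A belongs to shell 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:
    from .site_metrics import SiteTable

SHELL_WIDTH = 5.0
SHELL_HALF = 2.5


def assign_shell(d: float) -> int:
    """Shell index for a distance d >= 0 (A).

    Shell 0 is [0, 2.5]; shell k >= 1 is (5k - 2.5, 5k + 2.5].  Every
    non-negative distance maps to exactly one shell.
    """
    if not np.isfinite(d):
        raise ValueError("distance must be finite")
    if d < 0:
        raise ValueError(f"negative distance {d}")
    if d <= SHELL_HALF:
        return 0
    return int(math.ceil((d - SHELL_HALF) / SHELL_WIDTH))


@dataclass
class ShellSummary:
    """Per-shell counts, mean rates and raw rate values.

    Empty shells are absent from the mappings (not recorded as zero).
    """

    counts: Mapping[int, int]
    mean_K: Mapping[int, float]
    rate_values: Mapping[int, np.ndarray]

    @property
    def shells(self) -> list[int]:
        return sorted(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shell": self.shells,
                "count": [self.counts[s] for s in self.shells],
                "mean_K": [self.mean_K[s] for s in self.shells],
            }
        )


def shell_summary(
    tables: "SiteTable | Iterable[SiteTable]",
    by: str = "catalytic_distance",
) -> ShellSummary:
    """Summarize rates per shell, pooled across proteins residue-weighted.

    ``by="catalytic_distance"`` uses the precomputed shell column (distance
    to the nearest catalytic residue); ``by="interface_distance"`` re-bins by
    the distance to the nearest interface residue and requires at least one
    interface residue in every table.
    """
    if by not in ("catalytic_distance", "interface_distance"):
        raise ValueError(f"unknown stratification {by!r}")
    from .site_metrics import SiteTable  # noqa: F401  (runtime type check)

    if isinstance(tables, SiteTable):
        tables = [tables]
    frames = []
    for t in tables:
        df = t.df
        if by == "catalytic_distance":
            sub = df.loc[df["shell"] >= 0, ["shell", "K"]]
            if sub.empty:
                raise ValueError(f"{t.protein_id}: no catalytic-distance shells")
        else:
            if "d_interface" not in df.columns or not df["is_interface"].any():
                raise ValueError(f"{t.protein_id}: no interface residues")
            sub = pd.DataFrame(
                {
                    "shell": [assign_shell(x) for x in df["d_interface"]],
                    "K": df["K"].to_numpy(),
                }
            )
        frames.append(sub)
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled.dropna(subset=["K"])
    if pooled.empty:
        raise ValueError("no rated residues to summarize")
    grouped = pooled.groupby("shell")["K"]
    return ShellSummary(
        counts={int(s): int(g.size) for s, g in grouped},
        mean_K={int(s): float(g.mean()) for s, g in grouped},
        rate_values={int(s): g.to_numpy() for s, g in grouped},
    )


def binned_smooth(
    d_values, K_values, bin_width: float = 2.5
) -> list[tuple[float, float, float]]:
    """Binned-mean trend of rate against distance.

    A deterministic stand-in for a spline smoother: means over half-open
    bins [m*w, (m+1)*w), reported as (bin center, mean K, standard error of
    the mean).  Bins with fewer than 2 points carry no standard error (NaN).
    """
    d = np.asarray(d_values, dtype=float)
    k = np.asarray(K_values, dtype=float)
    if d.shape != k.shape:
        raise ValueError("d and K must have equal length")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if d.size == 0:
        return []
    idx = np.floor(d / bin_width).astype(int)
    out = []
    for m in sorted(set(idx)):
        vals = k[idx == m]
        center = (m + 0.5) * bin_width
        se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) >= 2 else float("nan")
        out.append((center, float(vals.mean()), se))
    return out
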