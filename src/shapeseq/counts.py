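"""RT-stop count tables: the sufficient statistic of a probing experiment.

Each aligned read reports where reverse transcription halted.  A stop at
modification site k (1-based, k in [1, n]) means the polymerase copied
positions k+1..primer and halted one nucleotide before the modification;
a cDNA that covers position 1 is a full-length extension.  Per target and
per channel the experiment is therefore summarised by the vector
X[1..n] of stop counts plus the full-length count X_full.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .targets import TargetRNA

#: Sentinel stop site for cDNAs that reach position 1 (full extension).
FULL_LENGTH = None

PLUS = "plus"
MINUS = "minus"
CHANNELS = (PLUS, MINUS)


@dataclass(frozen=True)
class StopObservation:
    """A single aligned read's inferred RT stop."""

    target: str
    stop_site: int | None  # 1-based site, or FULL_LENGTH (None)
    channel: str

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")


@dataclass
class FragmentCounts:
    """Per-target, per-channel RT-stop counts.

    ``X[k-1]`` counts stops at modification site k; ``X_full`` counts
    full-length cDNAs.  All entries are non-negative and their sum equals
    the number of uniquely aligned reads for this target/channel.
    """

    target: str
    channel: str
    X: np.ndarray
    X_full: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        if self.X.ndim != 1:
            raise ValueError("X must be a 1-D count vector")
        if (self.X < 0).any() or self.X_full < 0:
            raise ValueError("counts must be non-negative")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def total(self) -> int:
        """Uniquely aligned reads: X_full + sum(X)."""
        return int(self.X.sum()) + int(self.X_full)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentCounts):
            return NotImplemented
        return (
            self.target == other.target
            and self.channel == other.channel
            and self.X_full == other.X_full
            and np.array_equal(self.X, other.X)
        )


def tabulate_stops(observations: Iterable[StopObservation],
                   target: TargetRNA) -> dict[str, FragmentCounts]:
    """Tally stop observations into per-channel count tables.

    Raises if any observation belongs to a different target or carries a
    stop site outside [1, n] — that signals an aligner/coordinate bug, not
    a data property.
    """
    n = target.n
    vecs = {ch: np.zeros(n, dtype=np.int64) for ch in CHANNELS}
    fulls = {ch: 0 for ch in CHANNELS}
    for obs in observations:
        if obs.target != target.name:
            raise ValueError(f"observation for {obs.target!r} tabulated against {target.name!r}")
        if obs.stop_site is FULL_LENGTH:
            fulls[obs.channel] += 1
        elif 1 <= obs.stop_site <= n:
            vecs[obs.channel][obs.stop_site - 1] += 1
        else:
            raise ValueError(
                f"stop site {obs.stop_site} outside probed region [1, {n}] "
                f"for target {target.name!r}"
            )
    return {
        ch: FragmentCounts(target.name, ch, vecs[ch], fulls[ch]) for ch in CHANNELS
    }


def write_stop_table(counts: Iterable[FragmentCounts], path: str | Path) -> None:
    """Tab-separated stop counts: target, channel, site, count.

    Site is the 1-based modification site, or the string ``FULL`` for the
    full-length row.
    """
    rows = []
    for fc in counts:
        for k, c in enumerate(fc.X, start=1):
            rows.append((fc.target, fc.channel, str(k), int(c)))
        rows.append((fc.target, fc.channel, "FULL", int(fc.X_full)))
    pd.DataFrame(rows, columns=["target", "channel", "site", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_stop_table(path: str | Path) -> list[FragmentCounts]:
    """Inverse of :func:`write_stop_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"site": str})
    out = []
    for (target, channel), grp in df.groupby(["target", "channel"], sort=False):
        full = int(grp.loc[grp["site"] == "FULL", "count"].sum())
        body = grp[grp["site"] != "FULL"]
        sites = body["site"].astype(int).to_numpy()
        X = np.zeros(sites.max() if len(sites) else 0, dtype=np.int64)
        X[sites - 1] = body["count"].to_numpy()
        out.append(FragmentCounts(str(target), str(channel), X, full))
    return out
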