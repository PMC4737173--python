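"""Reactivity estimation: theta/rho profiles from (+)/(-) stop counts.

Model
-----
Reverse transcription walks 3'->5', so it reaches modification site k
only if it did not already stop at any site j > k.  Writing X_k for the
(+)-channel stop counts and X_full for full-length cDNAs, the number of
transcripts *arriving* at site k is ``sum_{i<=k} X_i + X_full`` and the
maximum-likelihood per-encounter stop probability at k is

    beta_k = X_k / (sum_{i<=k} X_i + X_full),

and identically gamma_k from the (-) channel, which measures natural
drop-off alone.  In the (+) channel a stop occurs through drop-off *or*
modification, 1 - beta_k = (1 - gamma_k)(1 - m_k), so the
modification-attributable signal is

    raw_k = ln(1 - gamma_k) - ln(1 - beta_k) = -ln(1 - m_k),

which under single-hit (Poisson) modification is proportional to the
modification rate at k.  Negative raw values (control stops exceeding
treated stops) are truncated to zero before normalisation.  Theta is raw
normalised to the probability simplex, and rho = n * theta is the
length-normalised reactivity whose mean over probed positions is 1:
rho > 1.25 is conventionally "high", 0.5-1.25 "moderate", < 0.5 "weak".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts import FragmentCounts
from .targets import TargetRNA

#: Missing-value sentinel used in SHAPE-style text files.
MISSING = -999.0

#: Default reactivity class boundaries (rho scale).
HIGH_THRESHOLD = 1.25
WEAK_THRESHOLD = 0.5

_CLAMP_EPS = 1e-6


def stop_frequencies(counts: FragmentCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-site RT stop frequencies with drop-off (arrival) denominators.

    Returns ``(freq, observed)``: freq[k-1] = X_k / (sum_{i<=k} X_i + X_full),
    and ``observed`` flags sites whose denominator is positive (sites never
    reached by RT are unobserved and get frequency 0).  A frequency of
    exactly 1 (every surviving transcript stopped) is clamped to 1 - 1e-6
    with a warning so the log transform stays finite.
    """
    X = counts.X.astype(float)
    arrivals = counts.X_full + np.cumsum(X)
    observed = arrivals > 0
    freq = np.zeros_like(X)
    np.divide(X, arrivals, out=freq, where=observed)
    if (freq >= 1.0).any():
        warnings.warn(
            f"target {counts.target!r}: all surviving transcripts stop at "
            "some site; frequency clamped to 1 - 1e-6",
            RuntimeWarning,
            stacklevel=2,
        )
        freq = np.minimum(freq, 1.0 - _CLAMP_EPS)
    return freq, observed


@dataclass
class RhoProfile:
    """Length-normalised reactivities for one target/probed region."""

    target: str
    rho: np.ndarray
    degenerate: bool = False
    observed: np.ndarray | None = None  # False where RT never reached the site
    source_replicates: int = 1

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.observed is None:
            self.observed = np.ones_like(self.rho, dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.rho)


def theta_to_rho(theta: np.ndarray, degenerate: bool = False) -> np.ndarray:
    """Length-normalised reactivity rho = n * theta (mean 1 over probed
    positions for non-degenerate profiles; all zeros when degenerate)."""
    theta = np.asarray(theta, dtype=float)
    return np.zeros_like(theta) if degenerate else len(theta) * theta


def classify_reactivity(rho_value: float,
                        high: float = HIGH_THRESHOLD,
                        weak: float = WEAK_THRESHOLD) -> str:
    """Reactivity class of a single rho value.

    Values above ``high`` are "high", below ``weak`` are "weak", and the
    closed interval [weak, high] (boundaries included) is "moderate".
    """
    if not np.isfinite(rho_value) or rho_value < 0:
        raise ValueError(f"rho must be finite and non-negative, got {rho_value}")
    if rho_value > high:
        return "high"
    if rho_value < weak:
        return "weak"
    return "moderate"


class ReactivityModel:
    """Maximum-likelihood reactivity model for one target.

    Parameters
    ----------
    plus, minus : FragmentCounts
        Stop counts from the reagent-treated (+) and solvent-control (-)
        channels; same target, same probed length.
    target : TargetRNA, optional
        Supplies the sequence for per-base annotation and masking.

    Examples
    --------
    >>> result = ReactivityModel(plus, minus).fit()
    >>> result.theta, result.rho
    >>> print(result.summary())
    """

    def __init__(self, plus: FragmentCounts, minus: FragmentCounts,
                 target: TargetRNA | None = None):
        if plus.n != minus.n:
            raise ValueError(
                f"channel length mismatch: (+) has {plus.n} sites, (-) has {minus.n}"
            )
        if plus.target != minus.target:
            raise ValueError("(+) and (-) counts belong to different targets")
        if target is not None and target.n != plus.n:
            raise ValueError("target probed length does not match count vectors")
        self.plus = plus
        self.minus = minus
        self.target = target

    def fit(self) -> "ReactivityResults":
        beta, obs_plus = stop_frequencies(self.plus)
        gamma, obs_minus = stop_frequencies(self.minus)
        raw = np.maximum(0.0, np.log1p(-gamma) - np.log1p(-beta))
        total = raw.sum()
        degenerate = total <= 0.0
        theta = np.zeros_like(raw) if degenerate else raw / total
        n = len(theta)
        rho = n * theta
        return ReactivityResults(
            model=self,
            beta=beta,
            gamma=gamma,
            raw=raw,
            theta=theta,
            rho=rho,
            degenerate=degenerate,
            observed=obs_plus & obs_minus,
        )


def estimate_theta(plus: FragmentCounts, minus: FragmentCounts,
                   target: TargetRNA | None = None) -> "ReactivityResults":
    """Functional shorthand for ``ReactivityModel(plus, minus).fit()``."""
    return ReactivityModel(plus, minus, target).fit()


@dataclass
class ReactivityResults:
    """Fitted reactivities for one target.

    ``theta`` sums to 1 (non-degenerate profiles), ``rho = n * theta`` has
    mean 1 over probed positions.  ``degenerate`` marks profiles with no
    positive treatment signal anywhere — a legitimate outcome for
    orthogonal-pair controls, reported as all-zero rather than an error.
    """

    model: ReactivityModel
    beta: np.ndarray
    gamma: np.ndarray
    raw: np.ndarray
    theta: np.ndarray
    rho: np.ndarray
    degenerate: bool
    observed: np.ndarray

    @property
    def n(self) -> int:
        return len(self.theta)

    @property
    def target_name(self) -> str:
        return self.model.plus.target

    def rho_profile(self) -> RhoProfile:
        return RhoProfile(self.target_name, self.rho.copy(),
                          degenerate=self.degenerate, observed=self.observed.copy())

    def classes(self) -> list[str]:
        return [classify_reactivity(r) for r in self.rho]

    def summary(self) -> pd.DataFrame:
        """Per-position table: position, base, beta, gamma, theta, rho, class."""
        seq = (self.model.target.probed_sequence
               if self.model.target is not None else "N" * self.n)
        return pd.DataFrame(
            {
                "position": np.arange(1, self.n + 1),
                "base": list(seq),
                "beta": self.beta,
                "gamma": self.gamma,
                "theta": self.theta,
                "rho": self.rho,
                "class": self.classes(),
                "observed": self.observed,
            }
        )

    def plot(self, ax=None):
        """Reactivity bar plot coloured by class (high/moderate/weak)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, self.n / 8), 3))
        colors = {"high": "#d62728", "moderate": "#ff7f0e", "weak": "#1f1f1f"}
        ax.bar(np.arange(1, self.n + 1), self.rho,
               color=[colors[c] for c in self.classes()])
        ax.axhline(HIGH_THRESHOLD, ls="--", lw=0.5, color="grey")
        ax.axhline(WEAK_THRESHOLD, ls=":", lw=0.5, color="grey")
        ax.set_xlabel("position")
        ax.set_ylabel(r"reactivity $\rho$")
        ax.set_title(self.target_name)
        return ax


# ---------------------------------------------------------------------------
# replicate aggregation and condition comparison


@dataclass
class ReplicateSet:
    """Positionwise mean and sample SD over replicate rho profiles."""

    target: str
    profiles: list[RhoProfile]
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ValueError("replicate aggregation needs at least 2 profiles")
        lengths = {p.n for p in self.profiles}
        if len(lengths) != 1:
            raise ValueError(f"replicate profiles differ in length: {sorted(lengths)}")
        mat = np.vstack([p.rho for p in self.profiles])
        self.mean = mat.mean(axis=0)
        self.sd = mat.std(axis=0, ddof=1)

    @property
    def n_replicates(self) -> int:
        return len(self.profiles)

    def mean_profile(self) -> RhoProfile:
        return RhoProfile(self.target, self.mean.copy(),
                          source_replicates=self.n_replicates)


def aggregate_replicates(profiles: Sequence[RhoProfile]) -> ReplicateSet:
    """Positionwise arithmetic mean and sample SD (n-1 denominator)."""
    return ReplicateSet(profiles[0].target, list(profiles))


def welch_one_sided(group_a: Sequence[float], group_b: Sequence[float],
                    direction: str = "greater") -> float:
    """One-sided Welch's t-test p-value.

    ``direction="greater"`` tests H1: mean(A) > mean(B); ``"less"`` the
    reverse.  Uses the Satterthwaite degrees-of-freedom approximation.
    Two constant, equal groups carry no evidence either way: p = 0.5 with
    a zero-variance warning.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("both groups constant and equal; p = 0.5",
                          RuntimeWarning, stacklevel=2)
            return 0.5
        # constant groups with different means: direction decides
        observed_greater = a.mean() > b.mean()
        return 0.0 if observed_greater == (direction == "greater") else 1.0
    res = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
    return float(res.pvalue)


def mask_by_base(profile: RhoProfile, target: TargetRNA,
                 keep_bases: set[str]) -> np.ndarray:
    """Mask positions whose base is outside ``keep_bases`` (NaN = missing).

    Used for DMS-mode analysis, where only A and C report reliably; the
    masked value is distinct from 0 (a real, weak reactivity).
    """
    keep = {b.upper().replace("T", "U") for b in keep_bases}
    if not keep:
        raise ValueError("keep_bases must be non-empty")
    if profile.n > target.n:
        raise ValueError("profile longer than the target's probed region")
    out = profile.rho.astype(float).copy()
    for i, base in enumerate(target.probed_sequence[: profile.n]):
        if base not in keep:
            out[i] = np.nan
    return out


# ---------------------------------------------------------------------------
# reactivity table I/O


def write_reactivity_table(result_or_profile, path: str | Path,
                           replicates: ReplicateSet | None = None) -> None:
    """TSV: target, position, base, theta, rho, class, mean, sd, n_reps.

    Unobserved positions carry the -999 sentinel in theta/rho columns.
    """
    if isinstance(result_or_profile, ReactivityResults):
        df = result_or_profile.summary()
        df.insert(0, "target", result_or_profile.target_name)
        theta = df.pop("theta").to_numpy().copy()
        rho = df.pop("rho").to_numpy().copy()
        observed = df.pop("observed").to_numpy()
        theta[~observed] = MISSING
        rho[~observed] = MISSING
        df["theta"] = theta
        df["rho"] = rho
        df = df[["target", "position", "base", "theta", "rho", "class"]]
    else:
        p: RhoProfile = result_or_profile
        rho = p.rho.copy()
        rho[~p.observed] = MISSING
        df = pd.DataFrame(
            {
                "target": p.target,
                "position": np.arange(1, p.n + 1),
                "base": "N",
                "theta": MISSING,
                "rho": rho,
                "class": [
                    classify_reactivity(r) if o else "NA"
                    for r, o in zip(p.rho, p.observed)
                ],
            }
        )
    if replicates is not None:
        df["mean"] = replicates.mean
        df["sd"] = replicates.sd
        df["n_reps"] = replicates.n_replicates
    df.to_csv(path, sep="\t", index=False)


def write_rdat(path: str | Path, target: TargetRNA, replicates: ReplicateSet,
               modifier: str = "1M7", structure: str | None = None) -> None:
    """Minimal RDAT export of replicate-averaged reactivities for community
    database deposit (one REACTIVITY row per replicate plus the error row)."""
    n = target.n
    with open(path, "w") as fh:
        fh.write("RDAT_VERSION\t0.34\n")
        fh.write(f"NAME\t{target.name}\n")
        fh.write(f"SEQUENCE\t{target.probed_sequence}\n")
        if structure is not None:
            fh.write(f"STRUCTURE\t{structure}\n")
        fh.write("OFFSET\t0\n")
        fh.write(f"SEQPOS\t{chr(9).join(str(i) for i in range(1, n + 1))}\n")
        fh.write(f"ANNOTATION\texperimentType:ChemicalMapping\tmodifier:{modifier}\n")
        for i, profile in enumerate(replicates.profiles, start=1):
            fh.write(f"ANNOTATION_DATA:{i}\treplicate:{i}\n")
        for i, profile in enumerate(replicates.profiles, start=1):
            vals = "\t".join(f"{v:.6g}" for v in profile.rho)
            fh.write(f"REACTIVITY:{i}\t{vals}\n")
        err = "\t".join(f"{v:.6g}" for v in replicates.sd)
        fh.write(f"REACTIVITY_ERROR:1\t{err}\n")


def read_reactivity_table(path: str | Path) -> dict[str, RhoProfile]:
    """Read profiles written by :func:`write_reactivity_table` (or deposited
    tables in the same layout); -999 marks unobserved positions."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for target, grp in df.groupby("target", sort=False):
        grp = grp.sort_values("position")
        rho = grp["rho"].to_numpy(dtype=float)
        observed = rho != MISSING
        rho = np.where(observed, rho, 0.0)
        out[str(target)] = RhoProfile(str(target), rho, observed=observed)
    return out
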