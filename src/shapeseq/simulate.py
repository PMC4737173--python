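"""Generative model of a targeted probing experiment.

The simulator mirrors the assumptions the estimator inverts, so that
parameter-recovery tests are meaningful end to end:

* reverse transcription walks sites n -> 1; at site k it terminates with
  the natural drop-off probability gamma_k in both channels, and in the
  (+) channel additionally with the per-encounter modification
  propensity theta_true_k (single-hit regime);
* every stop becomes a read pair: a channel handle, then target sequence
  in sense orientation from the 5'-most covered position, then adapter
  read-through when the fragment is shorter than the read;
* ligation dimers — RT primer joined directly to the adapter with no
  target insert and no handle — contaminate the library at a set rate.

Counts are drawn multinomially from the closed-form stop distribution,
so runs are exactly reproducible from the seed.  Sequencing error is off
by default (the estimator has no error model); a uniform substitution
rate exists solely to stress the aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from .counts import FULL_LENGTH, MINUS, PLUS, FragmentCounts
from .reactivity import ReactivityResults
from .reads import ReadPair
from .targets import TargetRNA, as_dna

#: Default per-site modification propensity range: about one modification
#: per molecule over a 50-nt probed region (the single-hit regime SHAPE
#: chemistry targets).
DEFAULT_THETA_SCALE = 0.05
#: Default per-site natural drop-off range (a few percent of transcripts
#: lost across a typical probed region).
DEFAULT_GAMMA_SCALE = 0.01

_IUPAC_CHOICES = {"R": "AG", "Y": "CT", "N": "ACGT", "W": "AT", "S": "CG",
                  "K": "GT", "M": "AC"}


@dataclass
class SimulationTruth:
    """Ground truth for one simulated target."""

    target: TargetRNA
    theta_true: np.ndarray  # per-encounter modification propensities, [0, 1)
    gamma_true: np.ndarray  # per-site natural drop-off probabilities, [0, 1)
    depth_plus: int = 100_000
    depth_minus: int = 100_000
    dimer_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        n = self.target.n
        if len(self.theta_true) != n or len(self.gamma_true) != n:
            raise ValueError("truth vectors must match the probed length n")
        for name, v in (("theta_true", self.theta_true), ("gamma_true", self.gamma_true)):
            if (v < 0).any() or (v >= 1).any():
                raise ValueError(f"{name} entries must lie in [0, 1)")
        if self.depth_plus <= 0 or self.depth_minus <= 0:
            raise ValueError("depths must be positive")
        if not 0 <= self.dimer_rate < 1:
            raise ValueError("dimer_rate must lie in [0, 1)")

    @property
    def theta_normalized(self) -> np.ndarray:
        """theta_true rescaled to the simplex (what the estimator recovers)."""
        s = self.theta_true.sum()
        return self.theta_true / s if s > 0 else np.zeros_like(self.theta_true)


def random_truth(target: TargetRNA, seed: int = 0,
                 theta_scale: float = DEFAULT_THETA_SCALE,
                 gamma_scale: float = DEFAULT_GAMMA_SCALE,
                 depth: int = 100_000,
                 dimer_rate: float = 0.0) -> SimulationTruth:
    """Random truth with uniform per-site propensities on realistic scales."""
    rng = np.random.default_rng(seed)
    n = target.n
    return SimulationTruth(
        target=target,
        theta_true=rng.uniform(0.0, theta_scale, size=n),
        gamma_true=rng.uniform(0.0, gamma_scale, size=n),
        depth_plus=depth,
        depth_minus=depth,
        dimer_rate=dimer_rate,
        seed=seed,
    )


def stop_distribution(stop_probs: np.ndarray) -> np.ndarray:
    """Closed-form fragment distribution of the n -> 1 stop process.

    Entry k-1 is P(stop at site k) = s_k * prod_{j>k} (1 - s_j); the last
    entry is P(full length) = prod_j (1 - s_j).
    """
    s = np.asarray(stop_probs, dtype=float)
    # survival past sites n..k+1, computed from the 3' end
    surv = np.concatenate([np.cumprod((1.0 - s)[::-1])[::-1], [1.0]])
    probs = np.append(s * surv[1:], surv[0])
    return probs


def simulate_stop_counts(truth: SimulationTruth) -> tuple[FragmentCounts, FragmentCounts]:
    """Draw (+) and (-) channel FragmentCounts from the stop-process model."""
    rng = np.random.default_rng(truth.seed)
    s_minus = truth.gamma_true
    s_plus = s_minus + (1.0 - s_minus) * truth.theta_true
    out = []
    for channel, s, depth in (
        (PLUS, s_plus, truth.depth_plus),
        (MINUS, s_minus, truth.depth_minus),
    ):
        draw = rng.multinomial(depth, stop_distribution(s))
        out.append(
            FragmentCounts(truth.target.name, channel, draw[:-1], int(draw[-1]))
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# read-level simulation


def _concrete_handle(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        c if c in "ACGT" else rng.choice(list(_IUPAC_CHOICES[c])) for c in pattern
    )


def _mutate(read: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return read
    bases = "ACGT"
    out = list(read)
    for i in range(len(out)):
        if rng.random() < error_rate:
            out[i] = rng.choice([b for b in bases if b != out[i]])
    return "".join(out)


def _read_pair_for_stop(
    stop_site: int | None,
    target: TargetRNA,
    handle: str,
    adapter: str,
    read_length: int,
    name: str,
    channel: str,
    error_rate: float,
    rng: np.random.Generator,
) -> ReadPair:
    tdna = as_dna(target.sequence)
    p = 1 if stop_site is FULL_LENGTH else stop_site + 1
    insert = tdna[p - 1 : target.rt_primer_end]
    molecule = handle + insert + adapter
    read1 = _mutate(molecule[:read_length], error_rate, rng)
    read2 = _revcomp(molecule)[:read_length]
    return ReadPair(read1=read1, read2=read2, qual1="I" * len(read1),
                    qual2="I" * len(read2), channel=channel, name=name)


def _revcomp(dna: str) -> str:
    return dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_reads(
    plus: FragmentCounts,
    minus: FragmentCounts,
    target: TargetRNA,
    plus_handle: str = "RRRY",
    minus_handle: str = "YYYR",
    adapter: str = "AGATCGGAAGAGC",
    read_length: int = 35,
    dimer_rate: float = 0.0,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[ReadPair]:
    """Expand stop-count tables into paired sequencing reads.

    Each counted stop becomes one read pair whose 5'-most covered target
    position encodes the stop; ``dimer_rate`` sets the fraction of
    primer+adapter ligation-dimer reads in the returned collection.  The
    round trip through the read-processing pipeline reproduces the input
    counts exactly at zero error/dimer rates.
    """
    if read_length < len(plus_handle) + 1:
        raise ValueError("read_length must exceed the handle length")
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    idx = 0
    for counts, pattern in ((plus, plus_handle), (minus, minus_handle)):
        sites: list[int | None] = [FULL_LENGTH] * counts.X_full
        for k, c in enumerate(counts.X, start=1):
            sites.extend([k] * int(c))
        for site in sites:
            handle = _concrete_handle(pattern, rng)
            pairs.append(
                _read_pair_for_stop(site, target, handle, adapter, read_length,
                                    f"read{idx}", counts.channel, error_rate, rng)
            )
            idx += 1
    n_signal = len(pairs)
    n_dimers = int(round(dimer_rate / (1.0 - dimer_rate) * n_signal)) if dimer_rate else 0
    dimer_molecule = as_dna(target.rt_primer_site_sequence) + adapter
    for _ in range(n_dimers):
        read1 = dimer_molecule[:read_length]
        pairs.append(
            ReadPair(read1=read1, read2=_revcomp(dimer_molecule)[:read_length],
                     qual1="I" * len(read1), name=f"dimer{idx}", is_dimer=True)
        )
        idx += 1
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def write_paired_fastq(pairs: list[ReadPair], path1: str | Path,
                       path2: str | Path, header: str = "") -> None:
    """Write simulated pairs as two FASTQ files.

    ``header`` (parameter provenance) cannot live inside FASTQ, so it is
    written alongside as ``<path1>.provenance``."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}\n{p.read1}\n+\n{p.qual1 or 'I' * len(p.read1)}\n")
            r2 = p.read2 or p.read1
            f2.write(f"@{p.name}\n{r2}\n+\n{p.qual2 or 'I' * len(r2)}\n")
    if header:
        with open(str(path1) + ".provenance", "w") as fh:
            fh.write(header.rstrip() + "\n")


def write_truth_table(truth: SimulationTruth, path: str | Path) -> None:
    """TSV of the simulation truth with a provenance header."""
    with open(path, "w") as fh:
        fh.write(
            f"# target={truth.target.name} n={truth.target.n} "
            f"depth_plus={truth.depth_plus} depth_minus={truth.depth_minus} "
            f"dimer_rate={truth.dimer_rate} seed={truth.seed}\n"
        )
        fh.write("site\ttheta_true\tgamma_true\n")
        for k, (t, g) in enumerate(zip(truth.theta_true, truth.gamma_true), start=1):
            fh.write(f"{k}\t{t:.8g}\t{g:.8g}\n")


# ---------------------------------------------------------------------------
# recovery metrics


def recovery_metrics(theta_hat, truth: SimulationTruth) -> dict[str, float]:
    """Compare an estimated theta profile against normalised truth.

    ``theta_hat`` may be a fitted :class:`ReactivityResults` or a bare
    array on the simplex.  Rank correlation (Spearman) is computed over
    sites with positive true propensity.
    """
    if isinstance(theta_hat, ReactivityResults):
        theta_hat = theta_hat.theta
    theta_hat = np.asarray(theta_hat, dtype=float)
    truth_norm = truth.theta_normalized
    if len(theta_hat) != len(truth_norm):
        raise ValueError("estimate and truth lengths differ")
    err = theta_hat - truth_norm
    positive = truth.theta_true > 0
    if positive.sum() >= 2:
        rank_corr = float(spearmanr(theta_hat[positive], truth_norm[positive]).statistic)
    else:
        rank_corr = float("nan")
    return {
        "max_abs_error": float(np.abs(err).max()),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "rank_correlation": rank_corr,
    }
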