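"""Design of spacer sequences between a stop codon and a terminator.

Tuning termination efficiency by moving a terminator away from the stop
codon requires inserts that do not themselves fold or pair with the
terminator hairpin (either would confound the distance effect). Candidate
spacers are rejection-sampled from uniform random DNA and screened for:

* overall GC fraction at or below a cap (low-GC sequences form weaker
  secondary structure);
* no run of consecutive G/C bases longer than a cap;
* no k-mer whose reverse complement occurs in a forbidden target (the
  terminator hairpin arms) or elsewhere in the spacer itself -- a cheap
  proxy for hairpin-competing base pairing, pluggable for a thermodynamic
  folder behind the same report interface.

A Shine-Dalgarno-like motif followed by a start codon at plausible spacing
is flagged as a warning only (an internal translation-initiation site would
re-couple translation, as seen with cryptic starts in natural inserts).
"""

from __future__ import annotations

import random
import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["SpacerSpec", "ScreenReport", "screen_sequence", "design_spacer"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_SD_RE = re.compile(r"AGGAGG|GGAGG|AGGAG")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SpacerSpec:
    """Constraints for spacer generation."""

    length: int
    max_gc_fraction: float = 0.5
    max_gc_run: int = 3
    kmer_k: int = 6
    forbidden_complement_targets: tuple = ()
    max_attempts: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not 0.0 < self.max_gc_fraction <= 1.0:
            raise ValueError("max_gc_fraction must be in (0, 1]")
        if self.kmer_k > self.length:
            raise ValueError("kmer_k must not exceed length")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        object.__setattr__(
            self,
            "forbidden_complement_targets",
            tuple(t.upper() for t in self.forbidden_complement_targets),
        )


@dataclass(frozen=True)
class ScreenReport:
    """Per-screen outcome for one candidate sequence."""

    sequence: str
    gc_fraction: float
    gc_pass: bool
    max_gc_run_observed: int
    gc_run_pass: bool
    offending_kmers: tuple  # (kmer, where) pairs
    kmer_pass: bool
    sd_like_warning: bool

    @property
    def passed(self) -> bool:
        return self.gc_pass and self.gc_run_pass and self.kmer_pass

    def failing_screens(self) -> list[str]:
        out = []
        if not self.gc_pass:
            out.append("gc_fraction")
        if not self.gc_run_pass:
            out.append("gc_run")
        if not self.kmer_pass:
            out.append("kmer_complement")
        return out


def _max_gc_run(seq: str) -> int:
    best = run = 0
    for base in seq:
        run = run + 1 if base in "GC" else 0
        best = max(best, run)
    return best


def _has_sd_like_site(seq: str) -> bool:
    """SD-like motif with a start codon 4-12 nt downstream (heuristic)."""
    for m in _SD_RE.finditer(seq):
        window = seq[m.end() + 4 : m.end() + 15]
        if "ATG" in window or "GTG" in window:
            return True
    return False


def screen_sequence(seq: str, spec: SpacerSpec) -> ScreenReport:
    """Evaluate every screen on ``seq``; pure, no randomness."""
    seq = seq.upper()
    if not seq or set(seq) - set("ACGT"):
        raise ValueError("sequence must be non-empty and contain only A/C/G/T")
    gc = sum(seq.count(b) for b in "GC") / len(seq)
    run = _max_gc_run(seq)

    offending: list[tuple[str, str]] = []
    k = spec.kmer_k
    if k <= len(seq):
        kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        for kmer in sorted(kmers):
            rc = reverse_complement(kmer)
            for t_idx, target in enumerate(spec.forbidden_complement_targets):
                if rc in target:
                    offending.append((kmer, f"target[{t_idx}]"))
            # reverse complement elsewhere in the spacer -> self-pairing risk;
            # a palindromic k-mer needs a second occurrence to pair, and a
            # G/C-free duplex is too weak to compete with a GC-rich hairpin
            if sum(kmer.count(b) for b in "GC") >= 2 and (
                (rc != kmer and rc in seq)
                or (rc == kmer and len(re.findall(f"(?={kmer})", seq)) >= 2)
            ):
                offending.append((kmer, "self"))

    return ScreenReport(
        sequence=seq,
        gc_fraction=gc,
        gc_pass=gc <= spec.max_gc_fraction,
        max_gc_run_observed=run,
        gc_run_pass=run <= spec.max_gc_run,
        offending_kmers=tuple(offending),
        kmer_pass=not offending,
        sd_like_warning=_has_sd_like_site(seq),
    )


def design_spacer(spec: SpacerSpec) -> tuple[str, ScreenReport]:
    """Rejection-sample a spacer passing all screens; deterministic per seed.

    Raises after ``max_attempts`` rejections, naming the screen that failed
    most often (the binding constraint).
    """
    rng = random.Random(spec.seed)
    fail_counts: dict[str, int] = {}
    for _ in range(spec.max_attempts):
        seq = "".join(rng.choice("ACGT") for _ in range(spec.length))
        report = screen_sequence(seq, spec)
        if report.passed:
            if report.sd_like_warning:
                warnings.warn(
                    "accepted spacer contains an SD-like motif with downstream "
                    "start codon; it may create an internal initiation site",
                    stacklevel=2,
                )
            return seq, report
        for name in report.failing_screens():
            fail_counts[name] = fail_counts.get(name, 0) + 1
    tightest = max(fail_counts, key=fail_counts.get)
    raise ValueError(
        f"constraints unsatisfiable within {spec.max_attempts} attempts; "
        f"tightest failing screen: {tightest}"
    )
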