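"""Readers and writers for the CSV/JSON/FASTA formats shared by all stages.

Conventions: comma-separated UTF-8 CSV with '.' decimals; '#'-prefixed
metadata header lines recording tool version, seed and parameters; JSON for
fit results and simulator configs; FASTA (Biopython-compatible plain text)
for sequences. Sequence positions are 0-based half-open internally; spacer
distances d are reported as the nt count between the last base of the stop
codon and the first base of the hairpin stem.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .coupling import CouplingParams, FitResult
from .quantification import GrowthSeries, TEMeasurement

__all__ = [
    "read_measurements",
    "read_constructs",
    "write_te_table",
    "read_te_table",
    "write_fit_json",
    "read_fit_json",
    "write_samples_csv",
    "write_fasta",
    "read_fasta",
]

MEASUREMENT_COLUMNS = ["construct_id", "replicate", "time_min", "od600", "f_rfp", "f_gfp"]
CONSTRUCT_COLUMNS = [
    "construct_id", "series", "distance_nt", "rfp_modified",
    "translation_coupled", "is_reference",
]


def _metadata_lines(seed=None, **params) -> str:
    lines = [f"# termcouple {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in params.items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_measurements(path) -> dict[str, list[GrowthSeries]]:
    """Parse a long-format measurement CSV into replicate GrowthSeries.

    Grouped by construct then replicate, time-sorted within each replicate
    (row order in the file is immaterial). Invariant violations are reported
    with the offending construct/replicate and 1-based data row numbers.
    """
    df = _read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV missing columns: {sorted(missing)}")
    bad_od = df.index[df["od600"] <= 0]
    if len(bad_od):
        raise ValueError(f"invalid OD (<= 0) at data row(s) {[i + 1 for i in bad_od[:5]]}")
    out: dict[str, list[GrowthSeries]] = {}
    for (cid, rep), sub in df.groupby(["construct_id", "replicate"], sort=True):
        sub = sub.sort_values("time_min")
        if sub["time_min"].duplicated().any():
            raise ValueError(f"duplicate time points for construct {cid!r} replicate {rep}")
        try:
            series = GrowthSeries(
                construct_id=str(cid),
                time=sub["time_min"].to_numpy(),
                od=sub["od600"].to_numpy(),
                f_rfp=sub["f_rfp"].to_numpy(),
                f_gfp=sub["f_gfp"].to_numpy(),
            )
        except ValueError as exc:
            raise ValueError(f"construct {cid!r} replicate {rep}: {exc}") from exc
        out.setdefault(str(cid), []).append(series)
    return out


def read_constructs(path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = set(CONSTRUCT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"construct CSV missing columns: {sorted(missing)}")
    for col in ("rfp_modified", "translation_coupled", "is_reference"):
        df[col] = df[col].astype(bool)
    if int(df["is_reference"].sum()) != 1:
        raise ValueError("construct table must declare exactly one reference")
    return df


def write_te_table(measurements, path, seed=None, **params) -> None:
    """TE table CSV with metadata header; accepts TEMeasurements or a frame."""
    if isinstance(measurements, pd.DataFrame):
        df = measurements
    else:
        df = pd.DataFrame([asdict(m) for m in measurements])
        if df.empty:
            df = pd.DataFrame(
                columns=["construct_id", "series", "distance_nt", "te", "te_se",
                         "method", "n_replicates"]
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(seed=seed, **params))
        df.to_csv(fh, index=False, float_format="%.12g")


def read_te_table(path) -> pd.DataFrame:
    return _read_csv(path)


def write_fit_json(result: FitResult, path, seed=None, **params) -> None:
    payload = {
        "tool": f"termcouple {__version__}",
        "seed": seed,
        **params,
        "te0": result.params.te0,
        "alpha": result.params.alpha,
        "offsets": dict(result.params.offsets),
        "cdf_convention": result.params.cdf_convention,
        "rss": result.rss,
        "n_points": result.n_points,
        "bootstrap_ci": result.bootstrap_ci,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_fit_json(path) -> FitResult:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    params = CouplingParams(
        te0=payload["te0"],
        alpha=payload["alpha"],
        offsets={str(k): int(v) for k, v in payload["offsets"].items()},
        cdf_convention=payload.get("cdf_convention", "inclusive"),
    )
    return FitResult(
        params=params,
        rss=payload.get("rss", float("nan")),
        n_points=payload.get("n_points", 0),
        bootstrap_ci=payload.get("bootstrap_ci"),
    )


def write_samples_csv(samples, path, seed=None, **params) -> None:
    """Simulator trajectory samples: trajectory, x, terminated, head_start, catch_up_pos."""
    df = pd.DataFrame(
        {
            "trajectory": range(len(samples)),
            "x": [s.x for s in samples],
            "terminated": [int(s.terminated) for s in samples],
            "head_start": [s.head_start for s in samples],
            "catch_up_pos": [s.catch_up_pos for s in samples],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(seed=seed, **params))
        df.to_csv(fh, index=False)


def write_fasta(records, path) -> None:
    """records: iterable of (name, sequence)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio.SeqIO import parse as seqio_parse

    return [(rec.id, str(rec.seq).upper()) for rec in seqio_parse(str(path), "fasta")]
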