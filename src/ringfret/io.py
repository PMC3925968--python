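"""Plain-text readers and writers for traces, manifests, truth and spectra.

Trace files are TSV (frame, time_s, donor_counts, acceptor_counts), one
file per molecule, tied together by a manifest CSV (molecule_id,
condition, file).  Spectra are two-column CSV (wavelength_nm, value) with a
mandatory header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import IntensityTrace, SpectrumPair

__all__ = [
    "write_trace",
    "read_trace",
    "write_dataset",
    "read_dataset",
    "write_spectrum",
    "read_spectrum",
]


def write_trace(trace: IntensityTrace, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(trace.frame_times.size),
            "time_s": trace.frame_times,
            "donor_counts": trace.donor_channel,
            "acceptor_counts": trace.acceptor_channel,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trace(path, condition: str = "", molecule_id: str = "") -> IntensityTrace:
    df = pd.read_csv(path, sep="\t")
    required = {"frame", "time_s", "donor_counts", "acceptor_counts"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace file {path} missing columns {required - set(df.columns)}")
    return IntensityTrace(
        frame_times=df["time_s"].to_numpy(),
        donor_channel=df["donor_counts"].to_numpy(),
        acceptor_channel=df["acceptor_counts"].to_numpy(),
        condition=condition,
        molecule_id=molecule_id or Path(path).stem,
    )


def write_dataset(traces: list[IntensityTrace], out_dir) -> Path:
    """Write one TSV per molecule plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in traces:
        fname = f"{tr.molecule_id}.tsv"
        write_trace(tr, out / fname)
        rows.append({"molecule_id": tr.molecule_id, "condition": tr.condition, "file": fname})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path) -> list[IntensityTrace]:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    traces = []
    for _, row in manifest.iterrows():
        traces.append(
            read_trace(
                manifest_path.parent / row["file"],
                condition=row["condition"],
                molecule_id=row["molecule_id"],
            )
        )
    return traces


def write_spectrum(spec: SpectrumPair, path) -> None:
    pd.DataFrame({"wavelength_nm": spec.wavelengths, "value": spec.values}).to_csv(
        path, index=False
    )


def read_spectrum(path) -> SpectrumPair:
    df = pd.read_csv(path)
    if not {"wavelength_nm", "value"}.issubset(df.columns):
        raise ValueError(f"spectrum file {path} must have columns wavelength_nm,value")
    return SpectrumPair(df["wavelength_nm"].to_numpy(), df["value"].to_numpy())
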