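"""Delimited-text readers/writers and optional mzML peak-list ingestion."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

PEAK_COLUMNS = ["sample_id", "batch_id", "rt_seconds", "mz", "intensity"]

__all__ = ["read_peaks", "write_peaks", "read_reference", "write_reference",
           "read_truth", "write_truth", "write_json", "read_json",
           "read_mzml_peaks"]


def write_peaks(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, sep="\t", index=False)


def read_peaks(path) -> pd.DataFrame:
    peaks = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak list {path} lacks columns: {missing}")
    return peaks


def write_reference(reference: pd.DataFrame, path) -> None:
    reference.to_csv(path, sep="\t", index=False)


def read_reference(path) -> pd.DataFrame:
    ref = pd.read_csv(path, sep="\t")
    required = ["metabolite_id", "monoisotopic_mass", "origin_flag"]
    missing = [c for c in required if c not in ref.columns]
    if missing:
        raise ValueError(f"reference {path} lacks columns: {missing}")
    return ref


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def read_mzml_peaks(path, sample_id: str, batch_id=0,
                    min_intensity: float = 0.0) -> pd.DataFrame:
    """Flatten an mzML file's MS1 centroids into the pipeline's peak-list form.

    Every (m/z, intensity) pair of every MS1 spectrum becomes one row with the
    spectrum's retention time in seconds; downstream VLM assignment is
    mass-only, so no centroid merging is attempted here.
    """
    from pyteomics import mzml as pymzml

    rows = []
    with pymzml.MzML(str(path)) as reader:
        for spectrum in reader:
            if spectrum.get("ms level", 1) != 1:
                continue
            rt = float(spectrum["scanList"]["scan"][0]["scan start time"])
            # pyteomics reports minutes unless the file says otherwise
            unit = spectrum["scanList"]["scan"][0].get("scan start time",
                                                       None)
            rt_seconds = rt * 60.0 if getattr(unit, "unit_info", "minute") \
                == "minute" else rt
            for mz, inten in zip(spectrum["m/z array"],
                                 spectrum["intensity array"]):
                if inten >= min_intensity:
                    rows.append((sample_id, batch_id, rt_seconds,
                                 float(mz), float(inten)))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)
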