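"""Readers and writers for the pipeline's on-disk formats.

* Fluorescence recordings: wide CSV (``roi_id, channel, v0, v1, ...`` with
  channel in {F, Fn}) plus a ``<stem>.meta.json`` sidecar carrying fs and
  metadata, or an HDF5 container with datasets ``/F``, ``/Fn`` and attributes
  ``fs``, ``animal_id``, ``genotype``, ``layer``.
* Spike data: spikes TSV (``unit_id, time_s``) + units TSV (``unit_id,
  depth_um``).
* LFP: flat little-endian float32, channel-interleaved, with a JSON sidecar
  (``n_channels, fs_raw, dtype, channel_depths``), or HDF5.
* Proteomics: abundance TSV (first column protein id, remaining columns
  samples) + samples TSV (``sample_id, group``); gene sets / regulator
  networks in GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .calcium import FluorescenceRecording, TransientSummary
from .lfp import LfpRecording
from .proteomics import AbundanceTable
from .units import SpikeUnit


# -- fluorescence -----------------------------------------------------------

def write_recording_csv(rec: FluorescenceRecording, path) -> Path:
    path = Path(path)
    rows = []
    for i in range(rec.n_rois):
        rows.append([f"roi{i:04d}", "F", *rec.F[i]])
        rows.append([f"roi{i:04d}", "Fn", *rec.Fn[i]])
    cols = ["roi_id", "channel", *[f"f{j}" for j in range(rec.n_frames)]]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    meta = {
        "fs": rec.fs,
        "animal_id": rec.animal_id,
        "genotype": rec.genotype,
        "layer": rec.layer,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, sort_keys=True))
    return path


def read_recording_csv(path, fs: float | None = None) -> FluorescenceRecording:
    path = Path(path)
    meta: dict = {}
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    df = pd.read_csv(path)
    frames = [c for c in df.columns if c not in ("roi_id", "channel")]
    F = df[df["channel"] == "F"].sort_values("roi_id")[frames].to_numpy(dtype=float)
    Fn = df[df["channel"] == "Fn"].sort_values("roi_id")[frames].to_numpy(dtype=float)
    return FluorescenceRecording(
        F=F,
        Fn=Fn,
        fs=fs if fs is not None else float(meta.get("fs", 30.0)),
        animal_id=str(meta.get("animal_id", "")),
        genotype=str(meta.get("genotype", "")),
        layer=str(meta.get("layer", "unknown")),
    )


def write_recording_h5(rec: FluorescenceRecording, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("F", data=rec.F)
        h5.create_dataset("Fn", data=rec.Fn)
        h5.attrs["fs"] = rec.fs
        h5.attrs["animal_id"] = rec.animal_id
        h5.attrs["genotype"] = rec.genotype
        h5.attrs["layer"] = rec.layer
    return path


def read_recording_h5(path) -> FluorescenceRecording:
    with h5py.File(path, "r") as h5:
        return FluorescenceRecording(
            F=h5["F"][()],
            Fn=h5["Fn"][()],
            fs=float(h5.attrs["fs"]),
            animal_id=str(h5.attrs.get("animal_id", "")),
            genotype=str(h5.attrs.get("genotype", "")),
            layer=str(h5.attrs.get("layer", "unknown")),
        )


def write_events_tsv(summaries: list[TransientSummary], fs: float, path) -> Path:
    rows = []
    for s in summaries:
        for ev in s.events:
            rows.append(
                {
                    "roi_id": s.roi_id,
                    "onset_s": ev.onset_frame / fs,
                    "peak_s": ev.peak_frame / fs,
                    "peak_dff": ev.peak_dff,
                }
            )
    pd.DataFrame(rows, columns=["roi_id", "onset_s", "peak_s", "peak_dff"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def write_summary_tsv(summaries: list[TransientSummary], path) -> Path:
    pd.DataFrame(
        [
            {"roi_id": s.roi_id, "count": s.count, "rate_per_min": s.rate_per_min,
             "class": s.activity_class}
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


# -- spikes -----------------------------------------------------------------

def write_spikes_tsv(units: list[SpikeUnit], spikes_path, units_path) -> tuple[Path, Path]:
    spike_rows = []
    unit_rows = []
    for u in units:
        unit_rows.append({"unit_id": u.unit_id, "depth_um": u.depth_um})
        for t in u.spike_times:
            spike_rows.append({"unit_id": u.unit_id, "time_s": t})
    pd.DataFrame(spike_rows, columns=["unit_id", "time_s"]).to_csv(
        spikes_path, sep="\t", index=False
    )
    pd.DataFrame(unit_rows, columns=["unit_id", "depth_um"]).to_csv(
        units_path, sep="\t", index=False
    )
    return Path(spikes_path), Path(units_path)


def read_spikes_tsv(spikes_path, units_path) -> list[SpikeUnit]:
    spikes = pd.read_csv(spikes_path, sep="\t")
    meta = pd.read_csv(units_path, sep="\t").set_index("unit_id")
    units = []
    for unit_id, grp in spikes.groupby("unit_id", sort=True):
        units.append(
            SpikeUnit(
                unit_id=str(unit_id),
                spike_times=np.sort(grp["time_s"].to_numpy(dtype=float)),
                depth_um=float(meta.loc[unit_id, "depth_um"]),
            )
        )
    return units


# -- LFP --------------------------------------------------------------------

def write_lfp_binary(rec: LfpRecording, path) -> Path:
    """Channel-interleaved little-endian float32 with a JSON sidecar."""
    path = Path(path)
    interleaved = rec.samples.T.astype("<f4")  # sample-major: s0c0 s0c1 ... s1c0
    interleaved.tofile(path)
    sidecar = {
        "n_channels": rec.n_channels,
        "fs_raw": rec.fs_raw,
        "dtype": "<f4",
        "channel_depths": None
        if rec.channel_depths is None
        else list(map(float, rec.channel_depths)),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, sort_keys=True))
    return path


def read_lfp_binary(path) -> LfpRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = np.fromfile(path, dtype=sidecar["dtype"])
    n_ch = int(sidecar["n_channels"])
    samples = raw.reshape(-1, n_ch).T.astype(float)
    depths = sidecar.get("channel_depths")
    return LfpRecording(
        samples=samples,
        fs_raw=float(sidecar["fs_raw"]),
        channel_depths=None if depths is None else np.asarray(depths, dtype=float),
    )


# -- proteomics -------------------------------------------------------------

def write_abundance_tsv(table: AbundanceTable, abundance_path, samples_path) -> tuple[Path, Path]:
    table.data.rename_axis("protein_id").to_csv(abundance_path, sep="\t")
    table.groups.rename_axis("sample_id").rename("group").to_csv(samples_path, sep="\t")
    return Path(abundance_path), Path(samples_path)


def read_abundance_tsv(abundance_path, samples_path, min_valid_per_group: int = 3) -> AbundanceTable:
    data = pd.read_csv(abundance_path, sep="\t", index_col=0)
    groups = pd.read_csv(samples_path, sep="\t", index_col=0)["group"]
    return AbundanceTable(data=data, groups=groups, min_valid_per_group=min_valid_per_group)


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> Path:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")
    return Path(path)
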