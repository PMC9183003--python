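"""Readers and writers for raw recordings (text and HDF5 dialects).

Text dialect (modelled on the OpenSignals plain-text convention): the file
opens with ``#``-prefixed lines — a one-line banner, a JSON metadata object
(device, sampling rate, column map, channel sites/wavelengths, period
table), and ``# EndOfHeader`` — followed by tab-separated data columns
``time_s  <site1>_<l1>  <site1>_<l2>  <site2>_<l1>  <site2>_<l2>``.  Values
are written with 17 significant digits so a text round trip is exact for
float64.

HDF5 dialect: datasets ``/channels/<site>/<wavelength_nm>``, root attributes
``sampling_rate_hz``, ``subject_id`` and ``periods_json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .constants import DEFAULT_CONSTANTS
from .recording import (
    ChannelIntensities,
    FormatError,
    IntensityRecording,
    Period,
)

DIALECTS = ("opensignals_txt", "hdf5")
_BANNER = "nirsfatigue fNIRS recording"


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
        return dialect
    return "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "opensignals_txt"


def _metadata(rec: IntensityRecording) -> dict:
    l1 = int(DEFAULT_CONSTANTS.lambda1_nm)
    l2 = int(DEFAULT_CONSTANTS.lambda2_nm)
    columns = ["time_s"] + [
        f"{ch.site}_{w}" for ch in rec.channels for w in (l1, l2)
    ]
    return {
        "device": "synthetic-or-imported fNIRS",
        "subject_id": rec.subject_id,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "resolution_bits": 16,
        "wavelengths_nm": [l1, l2],
        "columns": columns,
        "channels": [
            {"site": ch.site, "wavelengths_nm": [l1, l2]} for ch in rec.channels
        ],
        "periods": [[p.start_s, p.end_s, p.role] for p in rec.periods],
    }


def write_recording(rec: IntensityRecording, path, dialect: str | None = None) -> Path:
    """Serialise a recording; the dialect defaults from the file suffix."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "hdf5":
        with h5py.File(path, "w") as h5:
            h5.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
            h5.attrs["subject_id"] = rec.subject_id
            h5.attrs["periods_json"] = json.dumps(
                [[p.start_s, p.end_s, p.role] for p in rec.periods]
            )
            grp = h5.create_group("channels")
            l1 = int(DEFAULT_CONSTANTS.lambda1_nm)
            l2 = int(DEFAULT_CONSTANTS.lambda2_nm)
            for ch in rec.channels:
                g = grp.create_group(ch.site)
                g.create_dataset(str(l1), data=ch.intensity_l1)
                g.create_dataset(str(l2), data=ch.intensity_l2)
        return path

    meta = _metadata(rec)
    t = np.arange(rec.n_samples) / rec.sampling_rate_hz
    cols = [t] + [s for ch in rec.channels for s in (ch.intensity_l1, ch.intensity_l2)]
    with open(path, "w") as fh:
        fh.write(f"# {_BANNER}\n")
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("# EndOfHeader\n")
        for row in zip(*cols):
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")
    return path


def _read_text(path: Path) -> IntensityRecording:
    with open(path) as fh:
        lines = fh.readlines()
    header = []
    body_start = None
    for i, line in enumerate(lines):
        if line.startswith("#"):
            header.append(line[1:].strip())
            if header[-1] == "EndOfHeader":
                body_start = i + 1
                break
        else:
            break
    if body_start is None or len(header) < 2:
        raise FormatError(f"{path}: missing '#'-prefixed header terminated by EndOfHeader")
    try:
        meta = json.loads(header[1])
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: header line 2 is not valid JSON: {exc}") from exc
    for required in ("sampling_rate_hz", "columns", "channels", "periods"):
        if required not in meta:
            raise FormatError(f"{path}: header missing required field {required!r}")

    data = np.loadtxt(lines[body_start:], delimiter="\t", ndmin=2)
    columns = meta["columns"]
    if data.shape[1] != len(columns):
        raise FormatError(
            f"{path}: {data.shape[1]} data columns but header declares {len(columns)}"
        )
    by_name = {name: data[:, i] for i, name in enumerate(columns)}
    channels = []
    for ch in meta["channels"]:
        site = ch["site"]
        w1, w2 = ch["wavelengths_nm"]
        try:
            channels.append(ChannelIntensities(site, by_name[f"{site}_{w1}"], by_name[f"{site}_{w2}"]))
        except KeyError as exc:
            raise FormatError(f"{path}: header column map lacks {exc}") from exc
    return IntensityRecording(
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        channels=tuple(channels),
        periods=tuple(Period(*p) for p in meta["periods"]),
        subject_id=str(meta.get("subject_id", "S")),
    )


def _read_hdf5(path: Path) -> IntensityRecording:
    with h5py.File(path, "r") as h5:
        if "sampling_rate_hz" not in h5.attrs:
            raise FormatError(f"{path}: missing sampling_rate_hz attribute")
        rate = float(h5.attrs["sampling_rate_hz"])
        subject = str(h5.attrs.get("subject_id", "S"))
        periods = tuple(
            Period(*p) for p in json.loads(h5.attrs.get("periods_json", "[]"))
        )
        if "channels" not in h5:
            raise FormatError(f"{path}: missing /channels group")
        channels = []
        for site, grp in h5["channels"].items():
            wavelengths = sorted(grp.keys(), key=float)
            if len(wavelengths) != 2:
                raise FormatError(
                    f"{path}: channel {site} must hold exactly two wavelengths"
                )
            channels.append(
                ChannelIntensities(site, grp[wavelengths[0]][:], grp[wavelengths[1]][:])
            )
    return IntensityRecording(
        sampling_rate_hz=rate,
        channels=tuple(channels),
        periods=periods,
        subject_id=subject,
    )


def read_recording(path, dialect: str | None = None) -> IntensityRecording:
    """Read and validate a recording in either dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = _infer_dialect(path, dialect)
    return _read_hdf5(path) if dialect == "hdf5" else _read_text(path)


__all__ = ["read_recording", "write_recording", "DIALECTS"]
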