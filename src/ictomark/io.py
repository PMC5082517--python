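"""Reading and writing EEG segments and networks.

Two interchange formats are supported for segments:

* **CSV** — rows are samples, the header holds channel labels, and a JSON
  sidecar (``<file>.json``) carries the sampling rate.  Values are written
  at full double precision, so CSV round-trips bit-exactly.
* **EDF** — 16-bit European Data Format.  Reading goes through MNE's
  native EDF reader; writing uses the small writer below (EDF is a fixed
  ASCII header plus little-endian int16 records), with per-channel physical
  scaling, so round-trip error is bounded by one quantization step.

Arrays produced mid-pipeline (filtered segments, networks) are stored in
NumPy ``.npz`` containers with named fields; networks additionally export
an edge-list TSV for interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .network import FunctionalNetwork
from .segment import EEGSegment


class EEGIOError(IOError):
    pass


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_csv(seg: EEGSegment, path) -> Path:
    """Write samples x channels CSV plus a JSON sidecar with the sample rate."""
    path = Path(path)
    header = ",".join(seg.channel_labels)
    np.savetxt(path, seg.data.T, fmt="%.17g", delimiter=",",
               header=header, comments="")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"sample_rate": seg.sample_rate, "channel_labels": list(seg.channel_labels)}
    ))
    return path


def _read_csv(path: Path) -> EEGSegment:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise EEGIOError(
            f"no sampling rate available: sidecar {sidecar.name} not found"
        )
    meta = json.loads(sidecar.read_text())
    if "sample_rate" not in meta:
        raise EEGIOError(f"sidecar {sidecar.name} lacks a sample_rate field")
    with open(path) as fh:
        labels = [c.strip().upper() for c in fh.readline().strip().split(",")]
    if len(set(labels)) != len(labels):
        raise EEGIOError(f"duplicate channel labels in {path.name}")
    data = np.loadtxt(path, delimiter=",", skiprows=1).T
    return EEGSegment(data=data, sample_rate=float(meta["sample_rate"]),
                      channel_labels=tuple(labels), band="raw")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise EEGIOError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def edf_quantization_step(physical_max: float) -> float:
    """Physical size of one digital unit for a symmetric-range channel."""
    return 2.0 * physical_max / (_DIG_MAX - _DIG_MIN)


def write_edf(seg: EEGSegment, path) -> Path:
    """Write a 16-bit EDF file (physical units microvolts).

    Uses 1-second data records when the sampling rate is integral and the
    duration a whole number of seconds, otherwise a single record spanning
    the segment.  Per-channel symmetric physical ranges are rounded to 5
    significant digits so they fit the 8-character header fields exactly.
    """
    path = Path(path)
    n_ch, n_samp = seg.data.shape
    fs = seg.sample_rate
    if float(fs).is_integer() and n_samp % int(fs) == 0:
        spr = int(fs)                   # samples per record (per channel)
        n_rec = n_samp // spr
        rec_dur = "1"
    else:
        spr = n_samp
        n_rec = 1
        rec_dur = f"{n_samp / fs:.8g}"

    pmax = np.abs(seg.data).max(axis=1)
    pmax[pmax == 0] = 1.0
    # round the range up to 5 significant digits => fits "8 ascii", exact re-parse
    pmax = np.array([float(f"{v * (1 + 1e-5):.5g}") for v in pmax])
    step = 2.0 * pmax / (_DIG_MAX - _DIG_MIN)
    digital = np.rint(seg.data / step[:, None]).clip(_DIG_MIN, _DIG_MAX).astype("<i2")

    head = b"".join([
        _ascii(0, 8),
        _ascii("X", 80),
        _ascii("X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (n_ch + 1), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii(rec_dur, 8),
        _ascii(n_ch, 4),
    ])
    fields = [
        ("label", 16, list(seg.channel_labels)),
        ("transducer", 80, [""] * n_ch),
        ("dim", 8, ["uV"] * n_ch),
        ("pmin", 8, [f"{-v:.5g}" for v in pmax]),
        ("pmax", 8, [f"{v:.5g}" for v in pmax]),
        ("dmin", 8, [_DIG_MIN] * n_ch),
        ("dmax", 8, [_DIG_MAX] * n_ch),
        ("prefilter", 80, [""] * n_ch),
        ("spr", 8, [spr] * n_ch),
        ("reserved", 32, [""] * n_ch),
    ]
    sig_head = b"".join(
        b"".join(_ascii(v, width) for v in values) for _, width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(head + sig_head)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def _read_edf(path: Path) -> EEGSegment:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [c.upper() for c in raw.ch_names]
    if len(set(labels)) != len(labels):
        raise EEGIOError(f"duplicate channel labels in {path.name}")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts; pipeline works in uV
    return EEGSegment(data=data, sample_rate=float(raw.info["sfreq"]),
                      channel_labels=tuple(labels), band="raw")


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def read_eeg(path, format: str | None = None) -> EEGSegment:
    """Read an EEG segment from EDF or CSV (format inferred from the suffix).

    Data are returned in microvolts with upper-cased channel labels; the
    returned segment carries the ``raw`` band tag.
    """
    path = Path(path)
    if not path.exists():
        raise EEGIOError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise EEGIOError(f"unsupported format {fmt!r} (use 'edf' or 'csv')")


# ---------------------------------------------------------------------------
# Array containers
# ---------------------------------------------------------------------------

def save_segment(seg: EEGSegment, path) -> Path:
    """Lossless ``.npz`` container for a (possibly filtered) segment."""
    path = Path(path)
    np.savez(
        path,
        data=seg.data,
        sample_rate=seg.sample_rate,
        channel_labels=np.array(seg.channel_labels),
        band=seg.band,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_segment(path) -> EEGSegment:
    with np.load(path, allow_pickle=False) as z:
        return EEGSegment(
            data=z["data"],
            sample_rate=float(z["sample_rate"]),
            channel_labels=tuple(str(c) for c in z["channel_labels"]),
            band=str(z["band"]),
        )


def write_network(net: FunctionalNetwork, path) -> Path:
    """Dense network container (.npz): labels plus all matrices."""
    path = Path(path)
    np.savez(
        path,
        labels=np.array(net.labels),
        plf=net.plf,
        lag=net.lag,
        sig_threshold=net.sig_threshold,
        adjacency=net.adjacency,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_network(path) -> FunctionalNetwork:
    with np.load(path, allow_pickle=False) as z:
        return FunctionalNetwork(
            plf=z["plf"], lag=z["lag"], sig_threshold=z["sig_threshold"],
            adjacency=z["adjacency"], labels=tuple(str(c) for c in z["labels"]),
        )


def write_edge_list(net: FunctionalNetwork, path) -> Path:
    """Significant edges as TSV: node_a, node_b, plf, lag_rad."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tplf\tlag_rad\n")
        for a, b, plf, lag in net.edge_list():
            fh.write(f"{a}\t{b}\t{plf:.6f}\t{lag:.6f}\n")
    return path
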