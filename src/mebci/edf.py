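"""Minimal EDF/EDF+ reader and writer (16-bit, one annotation channel).

Covers what the toolkit needs: continuous multichannel records at a single
sampling rate, physical scaling, and EDF+ text annotations marking trial
onsets with their class label. Not a general-purpose EDF implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["EdfError", "write_edf", "read_edf", "trialset_to_edf", "trialset_from_edf"]


class EdfError(ValueError):
    pass


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise EdfError(f"header field too long: {text!r}")
    return b.ljust(width)


def write_edf(
    path,
    signals: np.ndarray,
    fs: float,
    labels,
    annotations=(),
    physical_dim: str = "uV",
    record_seconds: float = 1.0,
) -> None:
    """Write (samples, channels) float data plus EDF+ annotations.

    Data are scaled per channel to the full 16-bit digital range. The
    annotation channel is sized to hold the longest record's text.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise EdfError("signals must be (samples, channels)")
    n_samples, n_chan = signals.shape
    labels = list(labels)
    if len(labels) != n_chan:
        raise EdfError("one label per channel required")
    spr = int(round(fs * record_seconds))
    if abs(spr - fs * record_seconds) > 1e-9:
        raise EdfError("fs * record_seconds must be integer")
    n_records = math.ceil(n_samples / spr)
    pad = n_records * spr - n_samples
    if pad:
        signals = np.concatenate([signals, np.zeros((pad, n_chan))], axis=0)

    phys_min = signals.min(axis=0)
    phys_max = signals.max(axis=0)
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((signals - phys_min) * scale + dig_min).astype("<i2")

    # annotation TALs per record
    tals = []
    ann_sorted = sorted(annotations, key=lambda a: a[0])
    for rec in range(n_records):
        t0 = rec * record_seconds
        tal = f"+{t0:g}\x14\x14\x00"
        for onset, dur, text in ann_sorted:
            if t0 <= onset < t0 + record_seconds:
                tal += f"+{onset:g}\x15{dur:g}\x14{text}\x14\x00"
        tals.append(tal.encode("utf-8"))
    ann_bytes = max(len(t) for t in tals)
    ann_spr = math.ceil(ann_bytes / 2) + 1  # 2 bytes per "sample", spare room

    ns = n_chan + 1
    header_bytes = 256 + ns * 256
    head = b""
    head += _field("0", 8)
    head += _field("X X X X", 80)
    head += _field("Startdate X X X X", 80)
    head += _field("01.01.20", 8)
    head += _field("00.00.00", 8)
    head += _field(str(header_bytes), 8)
    head += _field("EDF+C", 44)
    head += _field(str(n_records), 8)
    head += _field(f"{record_seconds:g}", 8)
    head += _field(str(ns), 4)

    def sig_fields(width, values):
        return b"".join(_field(v, width) for v in values)

    chan_labels = labels + ["EDF Annotations"]
    head += sig_fields(16, chan_labels)
    head += sig_fields(80, [""] * ns)
    head += sig_fields(8, [physical_dim] * n_chan + [""])
    head += sig_fields(8, [f"{v:.6g}"[:8] for v in phys_min] + ["-1"])
    head += sig_fields(8, [f"{v:.6g}"[:8] for v in phys_max] + ["1"])
    head += sig_fields(8, [str(dig_min)] * n_chan + [str(dig_min)])
    head += sig_fields(8, [str(dig_max)] * n_chan + [str(dig_max)])
    head += sig_fields(80, [""] * ns)
    head += sig_fields(8, [str(spr)] * n_chan + [str(ann_spr)])
    head += sig_fields(32, [""] * ns)
    assert len(head) == header_bytes

    with open(path, "wb") as f:
        f.write(head)
        for rec in range(n_records):
            chunk = digital[rec * spr: (rec + 1) * spr, :]
            f.write(chunk.T.tobytes())
            tal = tals[rec].ljust(ann_spr * 2, b"\x00")
            f.write(tal)


def read_edf(path):
    """Read an EDF/EDF+ file -> (signals, fs, labels, annotations).

    ``signals`` is (samples, channels) in physical units; annotation channels
    are parsed into (onset, duration, text) triples.
    """
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256 or head[:8].strip() not in (b"0",):
            raise EdfError("not a valid EDF header")
        header_bytes = int(head[184:192])
        n_records = int(head[236:244])
        record_seconds = float(head[244:252])
        ns = int(head[252:256])
        sig_head = f.read(header_bytes - 256)

        def col(width, offset):
            start = offset * ns
            return [
                sig_head[start + i * width: start + (i + 1) * width]
                .decode("ascii", "replace").strip()
                for i in range(ns)
            ]

        off = 0
        labels = col(16, off); off += 16
        off += 80  # transducer
        off += 8  # dimension
        pmin = [float(x) for x in col(8, off)]; off += 8
        pmax = [float(x) for x in col(8, off)]; off += 8
        dmin = [int(x) for x in col(8, off)]; off += 8
        dmax = [int(x) for x in col(8, off)]; off += 8
        off += 80  # prefilter
        spr = [int(x) for x in col(8, off)]
        data = f.read()

    rec_len = sum(spr)
    raw = np.frombuffer(data, dtype="<i2")
    if len(raw) < n_records * rec_len:
        raise EdfError("truncated data section")
    raw = raw[: n_records * rec_len].reshape(n_records, rec_len)

    sig_idx = [i for i, lab in enumerate(labels) if lab != "EDF Annotations"]
    ann_idx = [i for i, lab in enumerate(labels) if lab == "EDF Annotations"]
    starts = np.concatenate([[0], np.cumsum(spr)])
    out = []
    for i in sig_idx:
        dig = raw[:, starts[i]: starts[i + 1]].reshape(-1).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        out.append(pmin[i] + (dig - dmin[i]) * gain)
    signals = np.stack(out, axis=1) if out else np.empty((0, 0))
    fs = spr[sig_idx[0]] / record_seconds if sig_idx else 0.0

    annotations = []
    for i in ann_idx:
        blob = raw[:, starts[i]: starts[i + 1]].tobytes()
        for tal in blob.split(b"\x00"):
            if not tal or b"\x14" not in tal:
                continue
            head_part, *texts = tal.split(b"\x14")
            if b"\x15" in head_part:
                onset_b, dur_b = head_part.split(b"\x15")
                dur = float(dur_b)
            else:
                onset_b, dur = head_part, 0.0
            try:
                onset = float(onset_b)
            except ValueError:
                continue
            for t in texts:
                if t:
                    annotations.append((onset, dur, t.decode("utf-8")))
    return signals, fs, [labels[i] for i in sig_idx], annotations


def trialset_to_edf(path, ts, protocol=None) -> None:
    """One subject's trials as a continuous EDF+ file with class annotations.

    Trials are laid out back to back with countdown/rest zero padding when a
    protocol is given; each task onset is annotated with the trial's label.
    """
    fs = ts.fs
    n_task = ts.data.shape[1]
    pre = int(round((protocol.countdown_seconds if protocol else 0.0) * fs))
    post = int(round((protocol.rest_seconds if protocol else 0.0) * fs))
    trial_len = pre + n_task + post
    total = trial_len * ts.n_trials
    signals = np.zeros((total, ts.n_channels))
    annotations = []
    for t in range(ts.n_trials):
        start = t * trial_len
        signals[start + pre: start + pre + n_task, :] = ts.data[t]
        annotations.append(
            ((start + pre) / fs, n_task / fs,
             f"{ts.labels[t]}:session{ts.session_ids[t]}")
        )
    labels = list(ts.channel_names) or [f"ch{i}" for i in range(ts.n_channels)]
    write_edf(path, signals, fs, labels, annotations)


def trialset_from_edf(path, expected_channels=None, classes=None):
    """Rebuild a TrialSet from an annotated EDF+ file.

    Raises listing any missing montage channels when ``expected_channels``
    is given; channels are re-ordered to match it.
    """
    from mebci.pipeline import TrialSet

    signals, fs, labels, annotations = read_edf(path)
    if expected_channels is not None:
        missing = [c for c in expected_channels if c not in labels]
        if missing:
            raise EdfError(f"missing montage channels: {missing}")
        order = [labels.index(c) for c in expected_channels]
        signals = signals[:, order]
        labels = list(expected_channels)
    trials, trial_labels, sessions = [], [], []
    for onset, dur, text in sorted(annotations):
        if ":" in text:
            cls, ses = text.split(":", 1)
            ses_id = int(ses.replace("session", "") or 0)
        else:
            cls, ses_id = text, 0
        if classes is not None and cls not in classes:
            continue
        i0 = int(round(onset * fs))
        i1 = i0 + int(round(dur * fs))
        trials.append(signals[i0:i1, :])
        trial_labels.append(cls)
        sessions.append(ses_id)
    if not trials:
        raise EdfError("no class annotations found")
    return TrialSet(
        np.stack(trials), tuple(trial_labels), fs, tuple(sessions),
        channel_names=tuple(labels),
    )
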