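"""Readers and writers for the pipeline's on-disk formats.

Conventions: CSV with comma separator, '.' decimal, UTF-8 and a header
row (tables with labels use TSV); WAV as 16-bit PCM; image stacks as
multi-page TIFF; metadata as JSON.  Every writer/reader pair round-trips
bit-exactly for text formats and sample-exactly for WAV/TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io.wavfile
import tifffile

from .datatypes import AreaCurve, AudioSignal, EMGRecording, ImageSequence, VelumCurve, Zone, ZoneLabels

__all__ = [
    "write_emg_csv", "read_emg_csv",
    "write_wav", "read_wav",
    "write_tiff", "read_tiff",
    "write_curve_csv", "read_curve_csv",
    "write_zones_tsv", "read_zones_tsv",
    "write_scenario", "read_scenario",
    "read_deposited_corpus",
]


def write_emg_csv(path, rec: EMGRecording) -> None:
    path = Path(path)
    names = [f"ch{m['id']}" for m in rec.channel_meta]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# rate={rec.rate:g}\n")
        fh.write(",".join(names) + "\n")
        np.savetxt(fh, rec.channels.T, delimiter=",", fmt="%.17g")


def read_emg_csv(path) -> EMGRecording:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# rate="):
            raise ValueError(f"{path}: missing '# rate=' header")
        rate = float(header.split("=", 1)[1])
        names = fh.readline().strip().split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    meta = [{"id": int(n.lstrip("ch")), "configuration": "bipolar"} for n in names]
    return EMGRecording(channels=data.T, rate=rate, channel_meta=meta)


def write_wav(path, a: AudioSignal) -> None:
    peak = np.max(np.abs(a.samples)) if a.samples.size else 0.0
    scale = 32767.0 / peak if peak > 1.0 else 32767.0
    pcm = np.round(a.samples * scale).astype(np.int16)
    scipy.io.wavfile.write(str(path), int(a.rate), pcm)


def read_wav(path) -> AudioSignal:
    rate, data = scipy.io.wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    return AudioSignal(samples=np.asarray(data, dtype=np.float64), rate=float(rate))


def write_tiff(path, seq: ImageSequence) -> None:
    tifffile.imwrite(
        str(path),
        seq.frames.astype(np.float32),
        metadata={"fps": seq.fps},
    )


def read_tiff(path, fps: float | None = None) -> ImageSequence:
    with tifffile.TiffFile(str(path)) as tf:
        frames = tf.asarray()
        if fps is None:
            meta = tf.shaped_metadata or tf.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            fps = float(meta.get("fps", 14.0))
    return ImageSequence(frames=np.clip(frames.astype(np.float64), 0, 1), fps=fps)


def write_curve_csv(path, values: np.ndarray, rate: float) -> None:
    """Two-column (time_s, value) CSV for area / velum curves."""
    t = np.arange(len(values)) / rate
    df = pd.DataFrame({"time_s": t, "value": values})
    df.to_csv(path, index=False, float_format="%.17g")


def read_curve_csv(path):
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy()
    rate = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
    return df["value"].to_numpy(), float(round(rate, 9))


def read_velum_csv(path) -> VelumCurve:
    values, rate = read_curve_csv(path)
    return VelumCurve(values=np.clip(values, 0, 1), rate=rate)


def write_zones_tsv(path, zones: ZoneLabels) -> None:
    rows = [(z.start, z.end, z.label) for z in zones.zones]
    pd.DataFrame(rows, columns=["start_s", "end_s", "class"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_zones_tsv(path, rate: float = 600.0) -> ZoneLabels:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    zones = [
        Zone(start=float(r[0]), end=float(r[1]), label=str(r[2]))
        for r in df.itertuples(index=False)
    ]
    span = (zones[0].start, zones[-1].end) if zones else (0.0, 0.0)
    n = int(round((span[1] - span[0]) * rate))
    t = span[0] + np.arange(n) / rate
    sw = np.zeros(n, dtype=np.int8)
    for z in zones:
        if z.label == "nasal":
            sw[(t >= z.start) & (t < z.end)] = 1
    return ZoneLabels(zones=zones, square_wave=sw, rate=rate, span=span)


def write_scenario(outdir, scenario) -> None:
    """Write a generated scenario: emg.csv, audio_mri.wav, audio_emg.wav,
    mri.tif, velum_true.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_emg_csv(outdir / "emg.csv", scenario.emg)
    write_wav(outdir / "audio_mri.wav", scenario.audio_mri)
    write_wav(outdir / "audio_emg.wav", scenario.audio_emg)
    write_tiff(outdir / "mri.tif", scenario.mri)
    write_curve_csv(
        outdir / "velum_true.csv", scenario.true_velum.values, scenario.true_velum.rate
    )
    cfg = scenario.config
    truth = {
        "nasal_intervals": [list(iv) for iv in scenario.true_nasal_intervals],
        "warp_knots_mri_to_emg": scenario.true_warp.knots.tolist(),
        "true_areas": scenario.true_areas.tolist(),
        "vowels": [list(v) for v in scenario.vowel_of_time],
        "config": {
            "n_utterances": cfg.n_utterances,
            "emg_rate": cfg.emg_rate,
            "mri_fps": cfg.mri_fps,
            "audio_rate_mri": cfg.audio_rate_mri,
            "audio_rate_emg": cfg.audio_rate_emg,
            "n_channels": cfg.n_channels,
            "burst_lead": cfg.burst_lead,
            "burst_snr": cfg.burst_snr,
            "seed": cfg.seed,
            "schedule": [
                [e.onset_time, e.kind, e.open_duration, e.vowel]
                for e in cfg.vowel_schedule
            ],
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1), encoding="utf-8")


def read_scenario(outdir) -> dict:
    """Read back a scenario directory into package types plus the truth
    dict (inverse of write_scenario up to PCM quantization)."""
    outdir = Path(outdir)
    truth = json.loads((outdir / "truth.json").read_text(encoding="utf-8"))
    velum_values, velum_rate = read_curve_csv(outdir / "velum_true.csv")
    return {
        "emg": read_emg_csv(outdir / "emg.csv"),
        "audio_mri": read_wav(outdir / "audio_mri.wav"),
        "audio_emg": read_wav(outdir / "audio_emg.wav"),
        "mri": read_tiff(outdir / "mri.tif", fps=truth["config"]["mri_fps"]),
        "true_velum": VelumCurve(values=np.clip(velum_values, 0, 1), rate=velum_rate),
        "truth": truth,
    }


def read_deposited_corpus(path):
    """Best-effort adapter for an unpacked deposited-corpus directory.

    Yields per-utterance dicts with whichever of the package's types can
    be recovered.  Directories written by :func:`write_scenario` round-trip
    losslessly; unrecognized layouts raise a descriptive error listing the
    files found.  A channel count other than 5 produces a warning only.
    """
    import warnings

    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"corpus directory not found: {path}")
    utterances = []
    candidates = [path] + sorted(p for p in path.iterdir() if p.is_dir())
    for d in candidates:
        if (d / "emg.csv").exists():
            rec = read_emg_csv(d / "emg.csv")
            if rec.n_channels != 5:
                warnings.warn(
                    f"{d}: expected 5 EMG channels, found {rec.n_channels}; proceeding",
                    stacklevel=2,
                )
            item = {"path": d, "emg": rec}
            if (d / "truth.json").exists():
                item.update(read_scenario(d))
            else:
                for name, reader in (
                    ("audio_mri.wav", read_wav),
                    ("audio_emg.wav", read_wav),
                    ("mri.tif", read_tiff),
                ):
                    if (d / name).exists():
                        item[name.split(".")[0]] = reader(d / name)
            utterances.append(item)
    if not utterances:
        found = sorted(str(p.relative_to(path)) for p in path.rglob("*") if p.is_file())
        raise ValueError(
            "unrecognized corpus layout under "
            f"{path}; files found: {found[:50]}"
        )
    return utterances
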