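"""Container and results-table I/O.

Segment collections and fitted TRF models are stored in HDF5 containers;
sweep results go to TSV with a comment header recording the package
version, a configuration hash and the master seed, so every artifact is
reproducible from its own metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .trf import LagWindow, SegmentPair, TRFModel

__all__ = [
    "save_segments",
    "load_segments",
    "save_model",
    "load_model",
    "write_results",
    "read_results",
    "write_cv_result",
    "save_wav",
    "write_manifest",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a configuration (dataclass or mapping)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_segments(path, segments: Sequence[SegmentPair]) -> None:
    """Write a segment collection to an HDF5 container."""
    if not segments:
        raise InvalidInputError("refusing to write an empty segment collection")
    with h5py.File(path, "w") as f:
        f.attrs["n_segments"] = len(segments)
        f.attrs["fs"] = segments[0].fs
        for i, seg in enumerate(segments):
            g = f.create_group(f"segments/{i:04d}")
            g.create_dataset("stimulus", data=seg.stimulus)
            g.create_dataset("response", data=seg.response)
            g.attrs["fs"] = seg.fs


def load_segments(path) -> list[SegmentPair]:
    """Read a segment collection written by :func:`save_segments`."""
    out = []
    with h5py.File(path, "r") as f:
        keys = sorted(f["segments"].keys())
        for k in keys:
            g = f[f"segments/{k}"]
            out.append(
                SegmentPair(g["stimulus"][()], g["response"][()], float(g.attrs["fs"]))
            )
    return out


def save_model(path, model: TRFModel) -> None:
    """Serialize a fitted TRF model to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=model.weights)
        f.create_dataset("bias", data=model.bias)
        f.attrs["tmin"] = model.lag_window.tmin
        f.attrs["tmax"] = model.lag_window.tmax
        f.attrs["fs"] = model.lag_window.fs
        f.attrs["lam"] = model.lam


def load_model(path) -> TRFModel:
    """Load a TRF model written by :func:`save_model`."""
    with h5py.File(path, "r") as f:
        return TRFModel(
            weights=f["weights"][()],
            bias=f["bias"][()],
            lag_window=LagWindow(
                float(f.attrs["tmin"]), float(f.attrs["tmax"]), float(f.attrs["fs"])
            ),
            lam=float(f.attrs["lam"]),
        )


def write_cv_result(cv, path) -> None:
    """Write a cross-validation result (accuracy per lambda) as TSV."""
    df = pd.DataFrame(
        {"lambda": cv.lambdas, "accuracy": cv.accuracy_per_lambda}
    )
    df["selected"] = (df["lambda"] == cv.best_lambda).astype(int)
    df.to_csv(path, sep="\t", index=False)


def save_wav(path, stimulus: np.ndarray, fs: float) -> None:
    """Export a stimulus vector as a 16-bit WAV file (peak-normalized)."""
    from scipy.io import wavfile

    x = np.asarray(stimulus, dtype=float).ravel()
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    wavfile.write(path, int(round(fs)), (x * 32767).astype(np.int16))


def write_results(
    result: pd.DataFrame,
    path,
    config=None,
    seed: int | None = None,
    version: str | None = None,
) -> None:
    """Write a sweep-result table as TSV with a provenance comment header."""
    if version is None:
        from . import __version__ as version
    lines = [f"# trfseg {version}"]
    if config is not None:
        lines.append(f"# config_hash {config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed {seed}")
    lines.append(f"# written {datetime.now(timezone.utc).isoformat()}")
    buf = _io.StringIO()
    result.to_csv(buf, sep="\t", index=False)
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_results(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results`, skipping the comment header."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_manifest(path, participants) -> None:
    """Write a cohort manifest TSV (participants, trials, truth summary)."""
    rows = []
    for p in participants:
        for t, seg in enumerate(p.trials):
            rows.append(
                dict(
                    participant_id=p.participant_id,
                    trial=t,
                    n_samples=seg.n_samples,
                    fs=seg.fs,
                    snr_db=p.snr_db,
                    is_outlier=int(t in p.outlier_trials),
                    kernel_mu_ch0=p.kernels[0].mu,
                    kernel_sigma=p.kernels[0].sigma,
                    kernel_freq=p.kernels[0].freq,
                )
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


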