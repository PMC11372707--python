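"""CSV/JSON readers and writers with reproducibility headers.

Every CSV written by the pipeline opens with ``#`` comment lines carrying
the package version, the run seed, and a hash of the effective config, so a
file can be regenerated exactly from its own header.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import InvalidArgumentError
from .preprocessing import ForceTrial
from .synthetic import SubjectProfile

TRIAL_COLUMNS = [
    "participant_id", "timepoint", "condition", "hand", "role", "trial",
    "sex", "group", "mvc_n", "rate_hz", "sample_index", "force_n",
]


def config_hash(cfg: dict) -> str:
    payload = json.dumps(cfg, sort_keys=True, default=str).encode("utf8")
    return hashlib.sha256(payload).hexdigest()[:16]


def _header(seed: Optional[int], cfg_hash: Optional[str]) -> str:
    lines = [f"# forcefluct v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if cfg_hash is not None:
        lines.append(f"# config_sha={cfg_hash}")
    return "\n".join(lines) + "\n"


def write_csv(df: pd.DataFrame, path, seed: Optional[int] = None,
              cfg_hash: Optional[str] = None, float_format: str = "%.10g") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    buf.write(_header(seed, cfg_hash))
    df.to_csv(buf, index=False, float_format=float_format)
    path.write_text(buf.getvalue())


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def trials_to_frame(trials: Iterable[ForceTrial]) -> pd.DataFrame:
    """Long-format table, one row per sample."""
    chunks = []
    for tr in trials:
        n = tr.samples.size
        chunks.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "timepoint": tr.timepoint,
            "condition": tr.condition,
            "hand": tr.hand,
            "role": tr.role,
            "trial": tr.trial_index,
            "sex": tr.sex,
            "group": tr.group,
            "mvc_n": tr.mvc_n,
            "rate_hz": tr.rate_hz,
            "sample_index": np.arange(n),
            "force_n": tr.samples,
        }))
    if not chunks:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(chunks, ignore_index=True)[TRIAL_COLUMNS]


def frame_to_trials(df: pd.DataFrame) -> List[ForceTrial]:
    """Inverse of :func:`trials_to_frame`."""
    missing = set(TRIAL_COLUMNS) - {"sex", "group"} - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"trial table missing columns {sorted(missing)}")
    trials = []
    keys = ["participant_id", "timepoint", "condition", "hand", "role", "trial"]
    for key, sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("sample_index")
        pid, timepoint, condition, hand, role, trial = key
        trials.append(ForceTrial(
            samples=sub["force_n"].to_numpy(dtype=float),
            rate_hz=float(sub["rate_hz"].iloc[0]),
            hand=hand, role=role, condition=condition,
            participant_id=str(pid), timepoint=int(timepoint),
            mvc_n=float(sub["mvc_n"].iloc[0]), trial_index=int(trial),
            group=_opt(sub, "group"), sex=_opt(sub, "sex"),
        ))
    return trials


def _opt(sub: pd.DataFrame, col: str):
    if col not in sub.columns:
        return None
    v = sub[col].iloc[0]
    return None if pd.isna(v) else str(v)


def subjects_to_frame(subjects: Iterable[SubjectProfile]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = dict(participant_id=s.id, group=s.group, sex=s.sex,
                   age_y=s.age_y, mvc_n=s.mvc_n, moca=s.moca,
                   random_intercept=s.random_intercept)
        for i, z in enumerate(s.cerad_z, start=1):
            row[f"cerad_z{i}"] = z
        rows.append(row)
    return pd.DataFrame(rows)


def write_json(obj: Dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
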