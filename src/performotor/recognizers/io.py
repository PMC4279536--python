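"""Versioned model container: a pickle with a format tag and version."""

from __future__ import annotations

import pickle
from pathlib import Path

FORMAT = "performotor-model"
VERSION = 1


def save_model(model, path, symptom: str = "") -> Path:
    payload = {
        "format": FORMAT,
        "version": VERSION,
        "symptom": symptom,
        "class": type(model).__name__,
        "model": model,
    }
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=4)
    return path


def load_model(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != FORMAT:
        raise ValueError(f"{path} is not a {FORMAT} container")
    if payload.get("version") != VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')}")
    return payload["model"]
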