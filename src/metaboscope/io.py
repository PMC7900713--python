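"""File IO: TIFF stacks, trace tables, truth/config JSON, MID tables."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .trace import CellTrace, frame_to_traces, traces_to_frame


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), stack)


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_traces_csv(path: str | Path, traces: list[CellTrace]) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[CellTrace]:
    return frame_to_traces(pd.read_csv(path))


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_mid_csv(path: str | Path, mids: list) -> None:
    """mid.csv: metabolite, n_carbons, corrected, residual, M+0..M+n."""
    rows = []
    for m in mids:
        row = {"metabolite": m.metabolite, "n_carbons": m.n_carbons,
               "corrected": m.corrected, "residual": m.residual}
        for i, v in enumerate(m.intensities):
            row[f"M+{i}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mid_csv(path: str | Path) -> list:
    from .isotopes import MID

    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        n = int(r["n_carbons"])
        vec = np.array([r[f"M+{i}"] for i in range(n + 1)], dtype=float)
        out.append(MID(str(r["metabolite"]), n, vec, corrected=bool(r["corrected"]),
                       residual=float(r.get("residual", 0.0))))
    return out


def write_irf_csv(path: str | Path, irf: np.ndarray) -> None:
    pd.DataFrame({"irf": irf}).to_csv(path, index=False)


def read_irf_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["irf"].to_numpy()
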