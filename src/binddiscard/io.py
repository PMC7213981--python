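"""CSV/JSON output helpers with provenance blocks."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__


def provenance(config: dict, seed=None) -> dict:
    """Provenance block: config hash, seed, package version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "package": "binddiscard",
        "version": __version__,
    }


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_trajectory_csv(path, traj) -> None:
    """Columns: t_min, nicd_up, nicd_p, nicd_tot, nicd_tot_norm."""
    import pandas as pd

    tot = traj.NICD_tot_t
    norm = tot / tot[-1] if tot[-1] else np.full_like(tot, np.nan)
    pd.DataFrame(
        {
            "t_min": traj.times,
            "nicd_up": traj.NICD_up_t,
            "nicd_p": traj.NICD_p_t,
            "nicd_tot": tot,
            "nicd_tot_norm": norm,
        }
    ).to_csv(path, index=False)


def write_grid_csv(path, grid) -> None:
    """Grid matrix as CSV plus a JSON sidecar with axes and fixed inputs."""
    import pandas as pd

    df = pd.DataFrame(
        grid.kp_values,
        index=grid.Gamma_up_values,
        columns=grid.NICD0_values,
    )
    df.index.name = "Gamma_up"
    df.to_csv(path)
    sidecar = Path(str(path) + ".json")
    write_json(
        sidecar,
        {
            "NICD0_values": grid.NICD0_values,
            "Gamma_up_values": grid.Gamma_up_values,
            "slope_normalized": grid.slope_normalized,
            "N_e": grid.N_e,
            "Gamma_p": grid.Gamma_p,
        },
    )
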