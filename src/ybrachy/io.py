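"""Run configuration, reproducibility manifests and comparison reports.

File formats for the tally and parameter objects live with their owning
classes (``tallies``, ``tg43``, ``film``); this module adds the JSON run
configuration consumed by the command line, a manifest that pins config
hash + seed + versions for bit-exact reruns, and the per-quantity comparison
report used to confront two parameter sets (or two published radial-dose
columns) with each other.
"""
from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["RunConfig", "write_manifest", "compare_profiles", "compare_parameters"]


@dataclass
class RunConfig:
    """JSON-backed configuration for the simulate/extract workflow."""

    source_file: Optional[str] = None      # None = bundled prototype
    spectrum_file: Optional[str] = None    # None = bundled spectrum
    phantom_medium: Optional[str] = "water"
    phantom_radius_cm: float = 50.0
    tally_radii_cm: Sequence[float] = tuple(np.arange(0.5, 10.01, 0.5))
    radial_half_width_cm: float = 0.1
    theta_step_deg: float = 10.0
    n_histories: int = 1_000_000
    seed: int = 0
    cutoff_kev: float = 10.0
    sigma_cs: float = 0.02
    output_dir: str = "."

    def __post_init__(self):
        if self.n_histories < 1_000:
            raise ValueError("n_histories must be at least 1e3")
        if self.cutoff_kev < 0:
            raise ValueError("cutoff energy must be non-negative")
        for f in (self.source_file, self.spectrum_file):
            if f is not None and not Path(f).exists():
                raise FileNotFoundError(f"configured input {f!r} does not exist")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        d = {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(d, indent=2))

    def digest(self) -> str:
        blob = json.dumps({k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                           for k, v in self.__dict__.items()}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path, config: Optional[RunConfig] = None, seed: Optional[int] = None,
                   inputs: Sequence[str] = (), outputs: Sequence[str] = (),
                   extra: Optional[dict] = None) -> dict:
    """Record everything needed to reproduce a run bit-exactly."""
    from . import __version__
    man = {
        "package": "ybrachy",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed if seed is not None else (config.seed if config else None),
        "config_digest": config.digest() if config else None,
        "config": json.loads(json.dumps(config.__dict__, default=list)) if config else None,
        "inputs": {str(p): _file_digest(p) for p in inputs},
        "outputs": {str(p): _file_digest(p) for p in outputs},
    }
    if extra:
        man.update(extra)
    Path(path).write_text(json.dumps(man, indent=2))
    return man


def compare_profiles(x, a, b, label: str = "g") -> pd.DataFrame:
    """Per-point relative difference |a - b| / b of two profiles on a common
    grid, plus a 'max' attribute row ordering; b is the reference."""
    x = np.asarray(x, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if not (len(x) == len(a) == len(b)):
        raise ValueError("profiles must share one grid")
    rel = np.abs(a - b) / np.abs(b)
    return pd.DataFrame({"x": x, f"{label}_a": a, f"{label}_b": b, "rel_diff": rel})


def compare_parameters(set_a, set_b) -> dict:
    """Per-quantity maximum relative differences between two parameter sets.

    Returns a report dict: Lambda and S_k relative differences, the g(r)
    difference table with its maximum and location, and the F(r,theta)
    difference table (common valid nodes only) with its maximum and location.
    """
    rep = {
        "lambda_rel_diff": abs(set_a.lambda_cgy_per_hu - set_b.lambda_cgy_per_hu)
                           / set_b.lambda_cgy_per_hu,
        "sk_rel_diff": abs(set_a.sk_u_per_mci - set_b.sk_u_per_mci) / set_b.sk_u_per_mci,
    }
    ga = set_a.g_table.set_index("r_cm")["g"]
    gb = set_b.g_table.set_index("r_cm")["g"]
    common = ga.index.intersection(gb.index)
    if len(common):
        dg = compare_profiles(common.to_numpy(), ga[common].to_numpy(),
                              gb[common].to_numpy(), "g")
        i = int(dg.rel_diff.idxmax())
        rep["g"] = dg
        rep["g_max_rel_diff"] = float(dg.rel_diff.max())
        rep["g_max_at_r_cm"] = float(dg.x[i])
    fa = set_a.f_table.set_index(["r_cm", "theta_deg"])["F"]
    fb = set_b.f_table.set_index(["r_cm", "theta_deg"])["F"]
    common = fa.index.intersection(fb.index)
    if len(common):
        both = pd.DataFrame({"F_a": fa[common], "F_b": fb[common]}).dropna()
        both["rel_diff"] = (both.F_a - both.F_b).abs() / both.F_b.abs()
        rep["F"] = both.reset_index()
        if len(both):
            imax = both.rel_diff.idxmax()
            rep["F_max_rel_diff"] = float(both.rel_diff.max())
            rep["F_max_at"] = tuple(float(v) for v in imax)
    return rep
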