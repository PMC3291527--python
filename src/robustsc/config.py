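"""Run configuration: a flat key=value file with strict parsing.

Unknown keys are rejected and malformed lines are reported with their line
number; a configuration round-trips losslessly through save/load.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Parameters of an end-to-end experiment run.

    ``out_dir`` is required; every other field has a documented default.
    ``lambda_grid`` is the grid of normalized decomposition trade-offs
    (0 means no robust-PCA prefilter) and ``k_list`` the retained nonzero
    counts evaluated in the reconstruction-SNR table.
    """

    out_dir: str
    seed: int = 0
    image_count: int = 40
    image_size: int = 64
    spectral_exponent: float = 1.0
    patch_size: int = 8
    n_patches: int = 2000
    lambda_grid: tuple = (0.0, 0.5)
    m_atoms: int = 128
    sc_k: int = 4
    epochs: int = 1
    solver: str = "sp"
    k_list: tuple = (1, 2, 4)
    rpca_tol: float = 1e-7
    rpca_max_iter: int = 300
    gabor_restarts: int = 5
    gabor_max_filters: int = 24

    def __post_init__(self) -> None:
        self.lambda_grid = tuple(float(v) for v in self.lambda_grid)
        self.k_list = tuple(int(v) for v in self.k_list)
        if self.solver not in ("sp", "sce"):
            raise ConfigError(f"unknown solver {self.solver!r}")
        if any(v < 0 for v in self.lambda_grid):
            raise ConfigError("lambda_grid values must be nonnegative")
        if any(k < 1 or k > self.m_atoms for k in self.k_list):
            raise ConfigError("k_list values must lie in [1, m_atoms]")
        if self.sc_k > self.patch_size**2:
            raise ConfigError("sc_k may not exceed the patch dimension")


_FIELD_TYPES = {f.name: f.type for f in fields(RunConfig)}
_REQUIRED = {"out_dir"}


def _format_value(value) -> str:
    if isinstance(value, tuple):
        return ",".join(_format_value(v) for v in value)
    return repr(value) if isinstance(value, float) else str(value)


def _parse_value(name: str, raw: str):
    kind = _FIELD_TYPES[name]
    raw = raw.strip()
    if kind == "tuple":
        items = [v for v in raw.split(",") if v.strip() != ""]
        return tuple(float(v) if "." in v or "e" in v.lower() else int(v)
                     for v in items)
    if kind == "int":
        return int(raw)
    if kind == "float":
        return float(raw)
    return raw


def save_config(config: RunConfig, path) -> None:
    lines = [f"{f.name} = {_format_value(getattr(config, f.name))}"
             for f in fields(RunConfig)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> RunConfig:
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = stripped.partition("=")
        key = key.strip()
        if key not in _FIELD_TYPES:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            values[key] = _parse_value(key, raw)
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key!r}: {exc}")
    missing = _REQUIRED - values.keys()
    if missing:
        raise ConfigError(f"missing required key(s): {sorted(missing)}")
    return RunConfig(**values)
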