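"""Flat key-value run configuration.

A run is reproducible from its config file plus its inputs; ``dump`` then
``load`` then ``dump`` is byte-identical (keys are written in a fixed
order, values in canonical form).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .errors import ConfigurationError


@dataclass
class RunConfig:
    """Every tunable of a discovery run, in one serialisable record."""

    backends: str = ""  # comma-separated sample=path pairs
    annotation: str = ""
    region: str = ""  # chrom[:start-end[:strand]] selection, empty = all
    mu: float = 5.0
    minsup: int = 51
    strict: bool = False
    mu_mode: str = "fixed"  # fixed | frac-max | frac-min
    smooth: bool = False
    f: float = 0.1
    iterations: int = 3
    pseudocount: float = 1.0
    ladder: str = ""  # comma-separated ascending mu levels
    flank: int = 1000
    chunk_size: int = 2_000_000
    chunk_overlap: int = 10_000
    min_samples: int = 1
    categories: str = "genic"  # comma-separated subset of genic,extended,intergenic
    stranded: bool = True
    outdir: str = "covmine_out"
    log_level: str = "INFO"
    seed: int = 0

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    def dumps(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                v = "true" if v else "false"
            elif isinstance(v, float):
                v = f"{v:g}"
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"{path}:{lineno}: expected key = value")
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        kwargs = {}
        known = {f.name: f for f in fields(cls)}
        for key, value in raw.items():
            if key not in known:
                raise ConfigurationError(f"unknown config key: {key!r}")
            typ = known[key].type
            if typ == "bool":
                kwargs[key] = value.lower() in ("true", "1", "yes")
            elif typ == "int":
                kwargs[key] = int(value)
            elif typ == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)
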