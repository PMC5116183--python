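"""Run configuration: the tunable thresholds and flags, YAML round-trip,
and the machine-readable run manifest."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Configuration for a reproducible run.

    Thresholds: ``long_extension_threshold`` splits drosomycin/plant from
    long-chain-toxin spacing (C9–C10 residues, default 10);
    ``short_nloop_threshold`` is the n-loop length at or below which the
    KCXN toxin heuristic fires (default 6).  Both must be positive.
    """

    input: str | None = None
    propeptides: str | None = None
    out_dir: str = "."
    template: str | None = None
    n: int = 10
    seed: int = 1
    long_extension_threshold: int = 10
    short_nloop_threshold: int = 6
    mrbayes: bool = True
    mytilin_exception: bool = True
    fmt: str = "fasta"
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.long_extension_threshold <= 0 or self.short_nloop_threshold <= 0:
            raise ValueError("thresholds must be positive integers")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), newline="\n"
        )

    def merged(self, **overrides) -> "RunConfig":
        """Copy with non-None overrides applied (flags beat file values)."""
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)


def write_manifest(config: RunConfig, out_dir: str | Path) -> Path:
    """Write the run manifest (config echo + tool version) as YAML."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_manifest.yaml"
    payload = {"tool": "csabref", "version": __version__, "config": asdict(config)}
    path.write_text(yaml.safe_dump(payload, sort_keys=True), newline="\n")
    return path
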