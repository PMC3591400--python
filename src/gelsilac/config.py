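"""Pipeline configuration: every analysis threshold in one flat record.

Serialised as a flat ``key = value`` text file (UTF-8, "#" comments); the
round trip through :meth:`PipelineConfig.to_file` / ``from_file`` is
lossless.  Defaults are the thresholds of the analysis this package
implements: peptide probability >= 0.70, protein probability >= 0.95,
>= 3 unique peptides for unambiguous identification, alpha = 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # thresholds
    peptide_p_min: float = 0.70
    protein_p_min: float = 0.95
    min_unique_peptides: int = 3
    alpha: float = 0.05
    # analysis choices
    scale_estimator: str = "sd"            # "sd" | "mad"
    outlier_mad_limit: float | None = None  # band-level MAD rejection, off
    ratio_orientation: str = "light_over_heavy"
    averaging_mode: str = "band_mean"      # "band_mean" | "pooled"
    # lane calibration
    lane_f1_bands: int = 65
    lane_f2_bands: int = 72
    lane_mw_top_kda: float = 250.0
    lane_mw_bottom_kda: float = 10.0
    # reproducibility
    seed: int = 1
    # simulation (used when no evidence files are supplied)
    sim_n_proteins: int = 500
    sim_frac_regulated: float = 0.1
    sim_effect_min_log2: float = 0.8
    sim_effect_max_log2: float = 4.5
    sim_noise_sd: float = 0.3
    sim_mixing_offset: float = 0.1
    sim_decoy_fraction: float = 0.5
    sim_n_one_channel: int = 1
    sim_extreme_threshold: float = 5.0
    sim_peptides_per_protein: float = 6.0
    sim_spillover: float = 0.2
    # inputs (optional; empty string = not supplied)
    evidence_f1: str = ""
    evidence_f2: str = ""
    fasta: str = ""
    annotation: str = ""

    def __post_init__(self) -> None:
        for name in ("peptide_p_min", "protein_p_min", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_unique_peptides < 1:
            raise ValueError("min_unique_peptides must be >= 1")
        if self.scale_estimator not in ("sd", "mad"):
            raise ValueError("scale_estimator must be 'sd' or 'mad'")
        if self.averaging_mode not in ("band_mean", "pooled"):
            raise ValueError("averaging_mode must be 'band_mean' or 'pooled'")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be in [0, 2^31)")

    # -- flat key=value round trip -----------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = ["# gelsilac pipeline configuration"]
        for f in fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} = {'' if v is None else v}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        values: dict = {}
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _parse(val, known[key].type)
        return cls(**values)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


def _parse(text: str, typ) -> object:
    t = str(typ)
    if text == "" and ("None" in t or t == "str"):
        return None if "None" in t else ""
    if t in ("<class 'int'>", "int"):
        return int(text)
    if t in ("<class 'float'>", "float") or "float" in t:
        return float(text)
    if t in ("<class 'bool'>", "bool"):
        return text.lower() in ("1", "true", "yes")
    return text
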