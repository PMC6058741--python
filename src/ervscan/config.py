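"""Pipeline configuration: one flat key-value file, lossless round-trips.

Every stage threshold lives here with its documented default (0.95 gap
induction, 10,000 bp locus gap, 0.90 placement weight, 15,000 bp assembly
flank, 0.5 half-length fraction).  Values are serialised as ``key = value``
lines; types are recovered from the dataclass annotations.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    # paths
    genome: str = ""
    references: str = ""
    reference_labels: str = ""
    queries: str = ""
    alignments_dir: str = ""
    # translated search
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_score: float = 100.0
    merge_gap: int = 1000
    profile_threshold: float = 10.0
    # LTR pairing
    ltr_min: int = 100
    ltr_max: int = 1000
    ltr_identity: float = 85.0
    ltr_spacing_min: int = 1001
    ltr_spacing_max: int = 15000
    # curation
    gap_induction_threshold: float = 0.95
    locus_max_gap: int = 10000
    half_length_fraction: float = 0.5
    alt_flank: int = 15000
    # placement
    placement_threshold: float = 0.90
    min_overlap: float = 0.30
    # expression
    multimap_policy: str = "primary"   # none | primary | fractional
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.multimap_policy not in ("none", "primary", "fractional"):
            raise ConfigurationError(
                f"unknown multimap policy {self.multimap_policy!r}")

    def save(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        values = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"line {lineno}: expected key = value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ConfigurationError(f"unknown configuration key {key!r}")
            ftype = fields[key].type
            if ftype == "int":
                values[key] = int(raw)
            elif ftype == "float":
                values[key] = float(raw)
            else:
                values[key] = raw
        return cls(**values)

    def digest(self) -> str:
        payload = "|".join(
            f"{f.name}={getattr(self, f.name)}"
            for f in dataclasses.fields(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
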