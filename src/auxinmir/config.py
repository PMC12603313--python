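"""Pipeline configuration.

Every threshold used anywhere in the pipeline is named here, with its
default, so that a run is fully described by (config, seed, inputs).
Config files are flat YAML key/value mappings; unknown keys are rejected
to catch typos early.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # --- ORF curation -------------------------------------------------
    min_aa: int = 50                    # minimum ORF length in residues

    # --- pairwise alignment ------------------------------------------
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0              # cost of opening a gap
    gap_extend: float = 1.0             # cost per additional gap column

    # --- TIR1/AFB receptor curation ----------------------------------
    fbox_min_identity: float = 0.35     # identity over the reference F-box span
    lrr_coverage_threshold: float = 0.80  # aligned fraction of the LRR region
    # --- ARF curation -------------------------------------------------
    dbd_min_identity: float = 0.35      # identity over the reference B3-DBD span
    dd_min_coverage: float = 0.50       # aligned fraction of the DD span
    dbd_max_mismatch: int = 1           # tolerated literal mismatches in SxxxxHGxxSxxR
    pb1_min_identity: float = 0.30      # identity over the reference PB1 span
    pb1_max_stretch: float = 1.5        # max aligned query extent / PB1 ref length
    md_min_len: int = 30                # minimum middle-domain length (aa)
    q_min: float = 0.10                 # Gln frequency floor for activator call
    pg_min: float = 0.15                # Pro+Gly frequency floor for repressor call
    top_k: int = 4                      # Q,S,L must all rank in the top_k residues

    # --- precursor identification ------------------------------------
    max_mismatch: int = 0               # mature-miRNA search mismatches
    flank: int = 150                    # nt of context folded either side of the miRNA
    max_window: int = 400               # hard cap on the folding window
    min_loop: int = 3                   # minimum hairpin loop length
    min_paired_frac: float = 0.6        # miRNA bases paired for an in-stem call
    rho_threshold: float = 0.5          # Spearman filter, strict ">"

    # --- target scoring / degradome ----------------------------------
    max_bulge: int = 1                  # window length may differ from miRNA by this
    max_penalty: float = 4.5            # site acceptance threshold
    max_category: int = 4               # keep degradome categories <= this

    # --- statistics ----------------------------------------------------
    alpha: float = 0.05                 # significance level for group tests

    # --- run control ----------------------------------------------------
    seed: int = 1
    outdir: str = "auxinmir_out"

    def validate(self) -> None:
        """Reject impossible settings before any compute happens."""
        positive = ["min_aa", "gap_open", "gap_extend", "flank", "max_window"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config key {name!r} must be positive, got {getattr(self, name)}")
        nonneg = ["max_mismatch", "max_bulge", "max_penalty", "dbd_max_mismatch"]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"config key {name!r} must be >= 0, got {getattr(self, name)}")
        fractions = [
            "fbox_min_identity", "lrr_coverage_threshold", "dbd_min_identity",
            "dd_min_coverage", "pb1_min_identity", "q_min", "pg_min",
            "min_paired_frac", "alpha",
        ]
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"config key {name!r} must lie in [0, 1], got {v}")
        if self.min_loop < 3:
            raise ValueError(f"min_loop must be >= 3, got {self.min_loop}")
        if not -1.0 <= self.rho_threshold <= 1.0:
            raise ValueError(f"rho_threshold must lie in [-1, 1], got {self.rho_threshold}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
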