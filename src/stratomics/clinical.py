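"""Clinical marker record for a single breast tumor sample.

Routine immunohistochemistry and staging markers (ER/PR/HER2 status,
menopausal status, grade, TNM, Ki-67, S-phase fraction) drive the first tier
of the drug rules; everything except ``patient_id`` may be unknown.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .errors import InputError

TRI_STATE = ("positive", "negative", "unknown")
MENOPAUSE = ("pre", "post", "unknown")
SAMPLE_ORIGIN = ("primary", "metastasis", "unknown")


@dataclass
class ClinicalRecord:
    patient_id: str
    er_status: str = "unknown"
    pr_status: str = "unknown"
    her2_status: str = "unknown"
    menopausal_status: str = "unknown"
    histopathological_subtype: str = "unknown"
    tumor_size_mm: Optional[float] = None
    grade: Optional[int] = None
    tnm: tuple = field(default_factory=lambda: ("TX", "NX", "MX"))
    ki67_percent: Optional[float] = None
    s_phase_fraction: Optional[float] = None
    sample_origin: str = "unknown"
    tumor_cell_fraction: Optional[float] = None
    biopsy_date: Optional[str] = None

    def __post_init__(self):
        if not self.patient_id:
            raise InputError("clinical record: patient_id is required")
        for name in ("er_status", "pr_status", "her2_status"):
            if getattr(self, name) not in TRI_STATE:
                raise InputError(f"clinical record: {name} must be one of {TRI_STATE}")
        if self.menopausal_status not in MENOPAUSE:
            raise InputError(f"clinical record: menopausal_status must be one of {MENOPAUSE}")
        if self.sample_origin not in SAMPLE_ORIGIN:
            raise InputError(f"clinical record: sample_origin must be one of {SAMPLE_ORIGIN}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise InputError("clinical record: grade must be 1, 2 or 3")
        for name, hi in (("ki67_percent", 100.0), ("s_phase_fraction", 100.0),
                         ("tumor_cell_fraction", 1.0)):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= hi):
                raise InputError(f"clinical record: {name}={v} outside [0, {hi}]")
        if self.tumor_size_mm is not None and self.tumor_size_mm < 0:
            raise InputError("clinical record: tumor_size_mm must be non-negative")
        self.tnm = tuple(self.tnm)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tnm"] = list(self.tnm)
        return d


def read_clinical(path) -> ClinicalRecord:
    """Read a clinical record from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InputError(f"{path}: expected a YAML mapping of clinical fields")
    known = {f for f in ClinicalRecord.__dataclass_fields__}
    extra = set(raw) - known
    if extra:
        raise InputError(f"{path}: unknown clinical fields {sorted(extra)}")
    try:
        return ClinicalRecord(**raw)
    except TypeError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_clinical(record: ClinicalRecord, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(record.to_dict(), fh, sort_keys=True)
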