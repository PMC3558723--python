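"""Survey configuration: every geometric threshold in one place.

All cutoffs that shape a verdict are fields here so that a report can state
its provenance and so alternative operationalizations (e.g. a different
upright/flat boundary) can be swapped in without touching analysis code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError


@dataclass(frozen=True)
class SurveyConfig:
    """Thresholds governing contact detection and dimer assessment.

    Attributes
    ----------
    contact_cutoff:
        Maximum heavy-atom distance (angstrom) for an inter-molecular
        contact. 4.5 A is the standard crystal-contact criterion.
    mate_radius:
        Radius (angstrom) used when generating symmetry mates. Must exceed
        ``contact_cutoff`` so no contact-bearing mate is missed.
    symmetry_min_angle:
        Minimum rotation angle (degrees) of the transformation relating two
        C-alpha copies for the pair to count as 2-fold symmetric.
    symmetry_max_screw:
        Maximum translation (angstrom) along the rotation axis for a
        symmetric pair; a true point 2-fold has zero screw.
    orientation_tilt_boundary:
        Tilt (degrees) of the dimer 2-fold axis relative to the membrane
        axes separating upright-side-by-side from flat-on-membrane.
    alignment_min_identity:
        Minimum sequence identity for transferring strand elements from the
        reference C-alpha sequence.
    model2_min_cf_fraction:
        Minimum combined C-strand + F-strand share of interface atoms for a
        dimer to be called consistent with the C/F-strand dimerization
        model.
    """

    contact_cutoff: float = 4.5
    mate_radius: float = 5.0
    symmetry_min_angle: float = 160.0
    symmetry_max_screw: float = 3.0
    orientation_tilt_boundary: float = 45.0
    alignment_min_identity: float = 0.30
    model2_min_cf_fraction: float = 0.5

    def __post_init__(self):
        if self.mate_radius <= self.contact_cutoff:
            raise ConfigError(
                "mate_radius must exceed contact_cutoff "
                f"({self.mate_radius} <= {self.contact_cutoff})"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "SurveyConfig":
        """Parse a ``key = value`` configuration file.

        Lines starting with ``#`` and blank lines are ignored. Unknown keys
        and unparseable values are hard errors naming the key.
        """
        fields = {f.name: f for f in dataclasses.fields(cls)}
        values: dict[str, float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key = value, got {raw!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ConfigError(f"unknown configuration key: {key!r}")
            try:
                values[key] = float(val.strip())
            except ValueError:
                raise ConfigError(f"key {key!r}: cannot parse value {val.strip()!r}")
        return cls(**values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
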