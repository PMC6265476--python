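"""Built-in structural-requirement presets and user overrides.

``TA``: two-gene toxin/antitoxin arrays — partner on either side, toxin
30-200 aa, antitoxin 50-150 aa, gap up to 50 bp, overlap up to 20 bp, with a
+/-100 aa profile-specific length allowance.

``RND``: efflux-pump arrays — partner upstream, pump 700-1500 aa, partner
100-1000 aa, gap up to 500 bp, overlap up to 20 bp.

``flex``: nearest-neighbour discovery with effectively unbounded lengths.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError
from .operon_filter import StructuralRequirements


@dataclass(frozen=True)
class Preset:
    name: str
    requirements: StructuralRequirements
    min_bitscore: float
    expected_length_deviation: int | None


_PRESETS: dict[str, Preset] = {
    "TA": Preset(
        name="TA",
        requirements=StructuralRequirements(
            orientation="either",
            hit_min_aa=30, hit_max_aa=200,
            partner_min_aa_up=50, partner_max_aa_up=150,
            partner_min_aa_down=50, partner_max_aa_down=150,
            max_distance_bp=50, max_overlap_bp=20,
        ),
        min_bitscore=20.0,
        expected_length_deviation=100,
    ),
    "RND": Preset(
        name="RND",
        requirements=StructuralRequirements(
            orientation="upstream",
            hit_min_aa=700, hit_max_aa=1500,
            partner_min_aa_up=100, partner_max_aa_up=1000,
            partner_min_aa_down=100, partner_max_aa_down=1000,
            max_distance_bp=500, max_overlap_bp=20,
        ),
        min_bitscore=20.0,
        expected_length_deviation=None,
    ),
    "flex": Preset(
        name="flex",
        requirements=StructuralRequirements(
            orientation="either",
            hit_min_aa=1, hit_max_aa=10**6,
            partner_min_aa_up=1, partner_max_aa_up=10**6,
            partner_min_aa_down=1, partner_max_aa_down=10**6,
            max_distance_bp=300, max_overlap_bp=300,
        ),
        min_bitscore=20.0,
        expected_length_deviation=None,
    ),
}


def preset_names() -> tuple[str, ...]:
    return tuple(_PRESETS)


def load_preset(name: str) -> Preset:
    """Return a named built-in preset; unknown names list the valid ones."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; valid presets: {', '.join(_PRESETS)}"
        ) from None


def merge_requirements(base: Preset | StructuralRequirements,
                       overrides: dict) -> StructuralRequirements:
    """Field-wise override of a preset's requirements, re-validated."""
    req = base.requirements if isinstance(base, Preset) else base
    return req.with_overrides(**overrides)


def requirements_to_dict(req: StructuralRequirements) -> dict:
    return {f: getattr(req, f) for f in req.__dataclass_fields__}


def requirements_from_dict(d: dict) -> StructuralRequirements:
    return StructuralRequirements(**d)


def parse_expected_lengths(path: str | Path,
                           default_deviation: int | None = None,
                           ) -> dict[str, tuple[int, int]]:
    """Parse a profile -> expected-length table.

    Rows have two columns (profile, expected aa; the global
    ``default_deviation`` applies) or three (plus a per-profile deviation).
    Duplicate profiles and non-numeric values are errors.
    """
    path = Path(path)
    table: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) not in (2, 3):
                raise ConfigError(
                    f"{path.name}:{lineno}: expected 2 or 3 columns")
            profile = cols[0]
            if profile in table:
                raise ConfigError(
                    f"{path.name}:{lineno}: duplicate profile {profile!r}")
            try:
                expected = int(cols[1])
                deviation = int(cols[2]) if len(cols) == 3 else default_deviation
            except ValueError:
                raise ConfigError(
                    f"{path.name}:{lineno}: non-numeric value") from None
            if deviation is None:
                raise ConfigError(
                    f"{path.name}:{lineno}: no per-profile deviation and no "
                    "global deviation supplied")
            if expected <= 0 or deviation < 0:
                raise ConfigError(
                    f"{path.name}:{lineno}: lengths must be positive")
            table[profile] = (expected, deviation)
    return table
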