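"""Registry of pathogenicity-prediction tools.

Each tool is described by its score orientation (whether a higher or a
lower score means more deleterious), the valid score range, the word the
tool itself uses for its deleterious class ("Damaging", "Disease
causing", ...), and a commonly used default threshold.  The orientation
is what lets every downstream operation (worst-score aggregation,
threshold filters, top-fraction ranking) treat heterogeneous scores
uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import yaml

from .errors import ConfigurationError

HIGHER = "higher_is_deleterious"
LOWER = "lower_is_deleterious"
ORIENTATIONS = (HIGHER, LOWER)


@dataclass(frozen=True)
class ToolMeta:
    name: str
    orientation: str
    valid_range: tuple[float, float]
    deleterious_label: str = ""
    default_threshold: Optional[float] = None

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(
                f"tool {self.name}: unknown orientation {self.orientation!r}"
            )
        lo, hi = self.valid_range
        if not lo < hi:
            raise ConfigurationError(f"tool {self.name}: empty range {self.valid_range}")

    @property
    def deleterious_comparator(self) -> str:
        """Comparator selecting the deleterious side of a threshold."""
        return "<" if self.orientation == LOWER else ">"


def score_column(tool: str) -> str:
    """Column name used for a tool's score on a variant table."""
    return f"score_{tool}"


def default_registry() -> dict[str, ToolMeta]:
    """Commonly used missense predictors with their conventional thresholds.

    Thresholds follow widespread clinical-report usage: SIFT < 0.05,
    PolyPhen-2 > 0.8, CADD (phred) > 20, REVEL > 0.75, etc.  All
    overridable via :func:`load_registry`.
    """
    tools = [
        ToolMeta("SIFT", LOWER, (0.0, 1.0), "Damaging", 0.05),
        ToolMeta("PolyPhen", HIGHER, (0.0, 1.0), "Possibly damaging", 0.8),
        ToolMeta("CADD", HIGHER, (0.0, 99.0), "", 20.0),
        ToolMeta("REVEL", HIGHER, (0.0, 1.0), "", 0.75),
        ToolMeta("MutPred", HIGHER, (0.0, 1.0), "", 0.5),
        ToolMeta("MutationTaster", HIGHER, (0.0, 1.0), "Disease causing", 0.5),
        ToolMeta("MutationAssessor", HIGHER, (-6.0, 6.0), "High", 3.5),
        ToolMeta("FATHMM", LOWER, (-17.0, 17.0), "Damaging", -1.5),
        ToolMeta("MetaSVM", HIGHER, (-2.0, 3.0), "Damaging", 0.0),
        ToolMeta("MetaLR", HIGHER, (0.0, 1.0), "Damaging", 0.5),
        ToolMeta("PROVEAN", LOWER, (-14.0, 14.0), "Damaging", -2.5),
    ]
    return {t.name: t for t in tools}


def load_registry(path) -> dict[str, ToolMeta]:
    """Read a tool registry from YAML.

    Layout::

        SIFT:
          orientation: lower_is_deleterious
          range: [0.0, 1.0]
          deleterious_label: Damaging
          default_threshold: 0.05
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("registry YAML must map tool name -> settings")
    registry = {}
    for name, cfg in raw.items():
        try:
            registry[name] = ToolMeta(
                name=name,
                orientation=cfg["orientation"],
                valid_range=tuple(cfg["range"]),
                deleterious_label=cfg.get("deleterious_label", ""),
                default_threshold=cfg.get("default_threshold"),
            )
        except KeyError as exc:
            raise ConfigurationError(f"tool {name}: missing registry key {exc}") from exc
    return registry
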