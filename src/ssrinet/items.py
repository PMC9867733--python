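"""The 17-item Hamilton Depression Rating Scale battery.

Each interviewer-rated item is scored on an ordinal scale (0-4 for the
affective and cognitive items plus somatic anxiety and hypochondriasis,
0-2 for the rest) and belongs to one of five symptom categories.
"""

from __future__ import annotations

from dataclasses import dataclass

CATEGORIES = ("affective", "cognitive", "arousal_somatic", "sleep", "insight")


@dataclass(frozen=True)
class ItemSpec:
    """Metadata for one rating-scale item."""

    name: str
    category: str
    scale_max: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.scale_max not in (2, 4):
            raise ValueError(f"scale_max must be 2 or 4, got {self.scale_max}")


def hdrs_battery() -> list[ItemSpec]:
    """The default 17-item battery: 2 affective, 4 cognitive, 7 arousal/somatic,
    3 sleep and 1 insight item."""
    return [
        ItemSpec("depressed_mood", "affective", 4),
        ItemSpec("psychic_anxiety", "affective", 4),
        ItemSpec("guilt", "cognitive", 4),
        ItemSpec("suicidal_thoughts", "cognitive", 4),
        ItemSpec("loss_of_interest", "cognitive", 4),
        ItemSpec("retardation", "cognitive", 4),
        ItemSpec("agitation", "arousal_somatic", 2),
        ItemSpec("somatic_anxiety", "arousal_somatic", 4),
        ItemSpec("general_somatic", "arousal_somatic", 2),
        ItemSpec("genital", "arousal_somatic", 2),
        ItemSpec("hypochondriasis", "arousal_somatic", 4),
        ItemSpec("gastrointestinal", "arousal_somatic", 2),
        ItemSpec("weight_loss", "arousal_somatic", 2),
        ItemSpec("insomnia_early", "sleep", 2),
        ItemSpec("insomnia_middle", "sleep", 2),
        ItemSpec("insomnia_late", "sleep", 2),
        ItemSpec("lack_of_insight", "insight", 2),
    ]


def item_names(items: list[ItemSpec] | None = None) -> list[str]:
    return [it.name for it in (items or hdrs_battery())]
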