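"""Default-settings handling: built-ins, config file, CLI flags.

Precedence is CLI flag > config file > built-in default.  The anonymous
tier is capped at 50 predicted products (values above are clamped with a
warning); registered users are unrestricted.  When a relative-reasoning
model is configured and no truncation strategy is named explicitly, ML
truncation is activated by default.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .engine import DEFAULT_MAX_LEVELS, DEFAULT_MAX_PRODUCTS, PredictionSettings
from .errors import ValidationError
from .reasoning import (
    LikelihoodTruncation,
    MetaRule,
    MetaRuleTruncation,
    MLTruncation,
    NoTruncation,
    RelativeReasoningModel,
    TruncationStrategy,
)

logger = logging.getLogger(__name__)

ANONYMOUS_PRODUCT_CAP = 50
TIERS = ("anonymous", "registered")

_CONFIG_KEYS = {
    "packages", "max_levels", "max_products", "truncation", "model",
    "probability_cutoff", "seed",
}


@dataclass
class DefaultSettings:
    """Persisted per-user defaults (maps 1:1 onto the config file)."""

    packages: list[str] = field(default_factory=list)
    truncation: str = "none"
    max_levels: int = DEFAULT_MAX_LEVELS
    max_products: int = DEFAULT_MAX_PRODUCTS
    user_tier: str = "anonymous"

    def __post_init__(self) -> None:
        if self.user_tier not in TIERS:
            raise ValidationError(f"user_tier must be one of {TIERS}")
        if self.user_tier == "anonymous" and self.max_products > ANONYMOUS_PRODUCT_CAP:
            raise ValidationError(
                f"anonymous tier allows at most {ANONYMOUS_PRODUCT_CAP} products"
            )


def load_meta_rules(path: "str | Path") -> list[MetaRule]:
    """Read a meta-rules file: JSON list of {winner, losers, description}."""
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, list):
        raise ValidationError("meta-rules file must contain a JSON list")
    return [
        MetaRule(
            winner=item["winner"],
            losers=tuple(item["losers"]),
            description=item.get("description", ""),
        )
        for item in doc
    ]


def load_model(path: "str | Path") -> RelativeReasoningModel:
    return RelativeReasoningModel.from_json(json.loads(Path(path).read_text()))


def parse_truncation_spec(spec: str, default_cutoff: float = 0.5) -> TruncationStrategy:
    """Parse a truncation spec string into a strategy object.

    Accepted forms: ``none``, ``likelihood:<category>``,
    ``meta:<meta-rules.json>``, ``ml:<model.json>[:<cutoff>]``.
    """
    parts = spec.split(":")
    kind = parts[0]
    if kind == "none":
        if len(parts) > 1:
            raise ValidationError("truncation 'none' takes no argument")
        return NoTruncation()
    if kind == "likelihood":
        if len(parts) != 2:
            raise ValidationError("expected likelihood:<category>")
        return LikelihoodTruncation(parts[1])
    if kind == "meta":
        if len(parts) != 2:
            raise ValidationError("expected meta:<meta-rules.json>")
        return MetaRuleTruncation(load_meta_rules(parts[1]))
    if kind == "ml":
        if len(parts) not in (2, 3):
            raise ValidationError("expected ml:<model.json>[:<cutoff>]")
        cutoff = float(parts[2]) if len(parts) == 3 else default_cutoff
        return MLTruncation(load_model(parts[1]), probability_cutoff=cutoff)
    raise ValidationError(
        f"unknown truncation strategy {kind!r}; "
        "expected none|likelihood|meta|ml"
    )


def read_config(path: "str | Path") -> dict:
    """Read and validate the TOML config file."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return doc


def resolve_settings(
    cli_flags: dict | None = None,
    config_file: "str | Path | None" = None,
    user_tier: str = "anonymous",
) -> PredictionSettings:
    """Merge CLI flags, config file and built-in defaults into settings.

    ``cli_flags`` entries with value ``None`` are treated as unset.  The
    anonymous product cap is clamped (with a warning) rather than rejected,
    so an over-ambitious config still yields a usable run.
    """
    if user_tier not in TIERS:
        raise ValidationError(f"user_tier must be one of {TIERS}")
    cli_flags = {k: v for k, v in (cli_flags or {}).items() if v is not None}
    config = read_config(config_file) if config_file else {}

    def pick(key: str, default):
        if key in cli_flags:
            return cli_flags[key]
        if key in config:
            return config[key]
        return default

    max_levels = int(pick("max_levels", DEFAULT_MAX_LEVELS))
    max_products = int(pick("max_products", DEFAULT_MAX_PRODUCTS))
    packages = list(pick("packages", []))
    seed = int(pick("seed", 0))
    truncation_spec = pick("truncation", None)
    model_path = pick("model", None)
    cutoff = float(pick("probability_cutoff", 0.5))

    if truncation_spec is not None and truncation_spec.startswith("ml:") and model_path:
        raise ValidationError(
            "contradictory settings: both an explicit ml truncation spec and "
            "a configured model were given"
        )
    if truncation_spec is not None:
        truncation = parse_truncation_spec(truncation_spec, default_cutoff=cutoff)
    elif model_path:
        # a configured model activates ML truncation by default
        truncation = MLTruncation(load_model(model_path), probability_cutoff=cutoff)
    else:
        truncation = NoTruncation()

    if user_tier == "anonymous" and max_products > ANONYMOUS_PRODUCT_CAP:
        logger.warning(
            "anonymous tier: max_products clamped from %d to %d",
            max_products, ANONYMOUS_PRODUCT_CAP,
        )
        max_products = ANONYMOUS_PRODUCT_CAP

    return PredictionSettings(
        max_levels=max_levels,
        max_products=max_products,
        truncation=truncation,
        packages=packages,
        seed=seed,
    )
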