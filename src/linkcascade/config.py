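"""Flat YAML run configuration: schema, id column, dialect, cascade settings."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .linkage import STAGES, LinkageConfig
from .querying import QueryConfig
from .schema import AttributeSchema

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the dataset paths."""

    schema: AttributeSchema
    id_column: str = "record_id"
    date_dialect: str = "DD-MM-YYYY"
    linkage: LinkageConfig = field(default_factory=LinkageConfig)

    def to_dict(self) -> dict:
        return {
            "id_column": self.id_column,
            "date_dialect": self.date_dialect,
            "threshold": self.linkage.threshold,
            "top_n": self.linkage.query.top_n,
            "fuzzy_min_similarity": self.linkage.query.fuzzy_min_similarity,
            "stages": list(self.linkage.stages_enabled),
            "attributes": [
                {"name": a.name, "kind": a.kind, "weight": a.weight}
                for a in self.schema
            ],
        }


def load_config(path: str | Path) -> RunConfig:
    """Read a run configuration from a flat YAML file.

    Required key: ``attributes`` (list of name/kind/weight mappings).
    Optional keys with defaults: ``id_column``, ``date_dialect``,
    ``threshold``, ``top_n``, ``fuzzy_min_similarity``, ``stages``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "attributes" not in raw:
        raise ValueError(f"{path}: config must define an 'attributes' list")
    schema = AttributeSchema([
        (a["name"], a["kind"], float(a.get("weight", 1.0)))
        for a in raw["attributes"]
    ])
    stages = tuple(raw.get("stages", STAGES))
    linkage = LinkageConfig(
        threshold=float(raw.get("threshold", 0.9)),
        query=QueryConfig(
            top_n=int(raw.get("top_n", 20)),
            fuzzy_min_similarity=float(raw.get("fuzzy_min_similarity", 0.5)),
        ),
        stages_enabled=stages,
    )
    return RunConfig(
        schema=schema,
        id_column=str(raw.get("id_column", "record_id")),
        date_dialect=str(raw.get("date_dialect", "DD-MM-YYYY")),
        linkage=linkage,
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration that :func:`load_config` round-trips losslessly."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
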