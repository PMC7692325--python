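"""Target-gene panels and probeset mappings.

The Notch assay reads the expression of a curated panel of direct
transcriptional targets of the NOTCH/RBPJ/MAML complex.  The shipped panel
(``notch_panel.yaml``) carries the 18 literature-evidenced direct target
genes plus a best-effort Affymetrix HG-U133Plus2.0 probeset mapping; both
are data, not code, and can be replaced by any config file with the same
schema:

.. code-block:: yaml

    pathway_name: NOTCH
    version: "..."
    genes:
      - {symbol: HES1, direction: 1}
    probesets:
      - {id: 203395_s_at, gene: HES1, included: true}
      - {id: 1234_at, gene: HES1, included: false, reason: intronic}

``direction`` is the regulation sign on pathway activation (+1 = induced).
Every gene in the shipped Notch panel is +1; the field exists so the same
machinery can serve panels with repressed targets.  Excluded probesets must
carry a reason code (e.g. ``intronic``, ``opposite_strand``,
``wrong_chromosome``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import PanelLookupError, ParseError, ValidationError

#: Reason codes for excluding a probeset from a gene's evidence set.
EXCLUSION_REASONS = frozenset(
    {"intronic", "opposite_strand", "wrong_chromosome", "anticorrelated",
     "constant", "not_in_calibration", "other"}
)

NOTCH_PANEL_RESOURCE = "notch_panel.yaml"


@dataclass(frozen=True)
class TargetGenePanel:
    """Ordered gene panel with per-gene regulation direction."""

    pathway_name: str
    genes: tuple[str, ...]
    direction: Mapping[str, int]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("panel must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise ValidationError(f"duplicate gene symbols in panel: {dupes}")
        for g in self.genes:
            if g not in self.direction:
                raise ValidationError(f"gene {g!r} has no direction entry")
            if self.direction[g] not in (-1, 1):
                raise ValidationError(f"direction for {g!r} must be +1 or -1")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class ProbesetEntry:
    probeset_id: str
    gene: str
    included: bool = True
    reason: str | None = None

    def __post_init__(self) -> None:
        if not self.included and not self.reason:
            raise ValidationError(
                f"excluded probeset {self.probeset_id!r} must carry a reason code"
            )
        if self.reason is not None and self.reason not in EXCLUSION_REASONS:
            raise ValidationError(
                f"unknown exclusion reason {self.reason!r} for {self.probeset_id!r}"
            )


@dataclass(frozen=True)
class ProbesetMap:
    """probeset_id -> (gene, included) mapping, order-preserving."""

    entries: tuple[ProbesetEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [e.probeset_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate probeset ids: {dupes}")

    @property
    def probeset_ids(self) -> tuple[str, ...]:
        return tuple(e.probeset_id for e in self.entries)

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.gene, None)
        return tuple(seen)

    def gene_of(self, probeset_id: str) -> str:
        for e in self.entries:
            if e.probeset_id == probeset_id:
                return e.gene
        raise PanelLookupError(f"unknown probeset {probeset_id!r}")

    def validate_against(self, panel: TargetGenePanel) -> None:
        """Every panel gene must map to at least one included probeset."""
        covered = {e.gene for e in self.entries if e.included}
        missing = [g for g in panel.genes if g not in covered]
        if missing:
            raise ValidationError(
                f"panel genes without any included probeset: {missing}"
            )


def probesets_for_gene(pmap: ProbesetMap, gene: str) -> list[str]:
    """Included probesets for ``gene``, in mapping order.

    A gene that appears in the map only through excluded probesets yields an
    empty list; a gene absent from the map altogether raises.
    """
    if gene not in pmap.genes:
        raise PanelLookupError(f"gene {gene!r} not present in probeset map")
    return [e.probeset_id for e in pmap.entries if e.gene == gene and e.included]


def _parse_config(doc: dict) -> tuple[TargetGenePanel, ProbesetMap]:
    try:
        genes = [(str(g["symbol"]), int(g.get("direction", 1))) for g in doc["genes"]]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed panel config: {exc}") from exc
    panel = TargetGenePanel(
        pathway_name=str(doc.get("pathway_name", "unnamed")),
        genes=tuple(g for g, _ in genes),
        direction={g: d for g, d in genes},
        version=str(doc.get("version", "unversioned")),
    )
    entries = []
    for p in doc.get("probesets", []):
        try:
            entries.append(
                ProbesetEntry(
                    probeset_id=str(p["id"]),
                    gene=str(p["gene"]),
                    included=bool(p.get("included", True)),
                    reason=p.get("reason"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(f"malformed probeset entry {p!r}: {exc}") from exc
    pmap = ProbesetMap(entries=tuple(entries))
    unknown = [e.probeset_id for e in pmap.entries if e.gene not in panel.genes]
    if unknown:
        raise ValidationError(f"probesets mapped to genes outside the panel: {unknown}")
    return panel, pmap


def load_config(path: str | Path | None = None) -> tuple[TargetGenePanel, ProbesetMap]:
    """Load a panel + probeset-map config; ``None`` loads the shipped Notch panel."""
    if path is None:
        text = (
            importlib.resources.files("notchscore")
            .joinpath("data", NOTCH_PANEL_RESOURCE)
            .read_text()
        )
    else:
        path = Path(path)
        if not path.exists():
            raise ParseError(f"panel config not found: {path}")
        text = path.read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"cannot parse panel config: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError("panel config must be a mapping")
    return _parse_config(doc)


def load_panel(path: str | Path | None = None) -> TargetGenePanel:
    """Load only the gene panel from a config file (shipped default if ``None``)."""
    return load_config(path)[0]


def load_probeset_map(path: str | Path | None = None) -> ProbesetMap:
    return load_config(path)[1]


def save_config(
    panel: TargetGenePanel, pmap: ProbesetMap, path: str | Path
) -> None:
    """Serialize panel + map to the YAML dialect read by :func:`load_config`."""
    doc = {
        "pathway_name": panel.pathway_name,
        "version": panel.version,
        "genes": [
            {"symbol": g, "direction": int(panel.direction[g])} for g in panel.genes
        ],
        "probesets": [
            {
                "id": e.probeset_id,
                "gene": e.gene,
                "included": e.included,
                **({"reason": e.reason} if e.reason else {}),
            }
            for e in pmap.entries
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def make_panel(
    genes: Iterable[str],
    pathway_name: str = "custom",
    version: str = "unversioned",
    direction: Mapping[str, int] | None = None,
) -> TargetGenePanel:
    """Convenience constructor; default direction is +1 for every gene."""
    genes = tuple(genes)
    direction = dict(direction) if direction else {g: 1 for g in genes}
    return TargetGenePanel(pathway_name, genes, direction, version)
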