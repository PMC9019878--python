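"""Molecular alterations: parsing, common-variant filtering, risk tiers, weights.

An :class:`Alteration` is one molecular event observed in a fine-needle
aspirate — an SNV (e.g. ``BRAF V600E``), an indel, a gene fusion
(e.g. ``ETV6-NTRK3``) or an expression flag.  Alterations drive two things
downstream: the additive genomic-classifier score (via a :class:`WeightTable`)
and the qualitative risk tier used in the alteration summaries.

The tier semantics follow the standard thyroid-nodule molecular risk
partition: BRAF V600E, TERT promoter mutations and oncogenic fusions are
near-deterministic markers of malignancy (*high risk*); RAS-family mutations
and BRAF K601E mark follicular-patterned neoplasia without implying carcinoma
(*RAS-like*); everything else is *other*.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import AlterationParseError, DomainError, LoadError

__all__ = [
    "AlterationKind",
    "RiskTier",
    "Alteration",
    "TierMap",
    "DEFAULT_TIER_MAP",
    "RAS_FAMILY",
    "parse_alteration",
    "parse_alteration_list",
    "format_alteration",
    "format_alteration_list",
    "filter_common_variants",
    "assign_tier",
    "WeightTable",
    "DEFAULT_WEIGHT_TABLE",
    "read_weight_table",
    "write_weight_table",
    "read_vcf_alterations",
]

COMMON_VARIANT_THRESHOLD = 0.001  # population frequency above which a variant is a common SNP

RAS_FAMILY = frozenset({"NRAS", "HRAS", "KRAS"})


class AlterationKind(str, enum.Enum):
    SNV = "snv"
    INDEL = "indel"
    FUSION = "fusion"
    EXPRESSION = "expression"


class RiskTier(str, enum.Enum):
    HIGH_RISK = "high_risk"
    RAS_LIKE = "ras_like"
    OTHER = "other"


_GENE_RE = re.compile(r"^[A-Za-z0-9_.]+$")
_FUSION_RE = re.compile(r"^[A-Za-z0-9_.]+-[A-Za-z0-9_.]+$")
_KIND_TOKENS = {k.value for k in AlterationKind}


@dataclass(frozen=True)
class Alteration:
    """One molecular event.

    For fusions ``gene`` and ``detail`` both hold the hyphenated partner pair
    (``"ETV6-NTRK3"``): the pair *is* the event's identity and the detail
    field is required to name both partners.
    """

    gene: str
    kind: AlterationKind = AlterationKind.SNV
    detail: str = ""
    population_frequency: float | None = None

    def __post_init__(self):
        if not self.gene:
            raise DomainError("alteration gene must be non-empty")
        if self.kind is AlterationKind.FUSION and not _FUSION_RE.match(self.detail):
            raise DomainError(
                f"fusion detail must name two partners as A-B, got {self.detail!r}"
            )
        pf = self.population_frequency
        if pf is not None and not (0.0 <= pf <= 1.0):
            raise DomainError(f"population_frequency must be in [0, 1], got {pf}")

    def with_frequency(self, freq: float | None) -> "Alteration":
        return replace(self, population_frequency=freq)


def parse_alteration(text: str) -> Alteration:
    """Parse ``GENE[:DETAIL][:KIND]`` or ``GENE1-GENE2:fusion``.

    The kind is inferred as ``fusion`` when the leading token is a hyphenated
    partner pair, ``snv`` otherwise, unless a trailing kind token states it.

    >>> parse_alteration("BRAF:V600E").detail
    'V600E'
    >>> parse_alteration("ETV6-NTRK3:fusion").kind
    <AlterationKind.FUSION: 'fusion'>
    """
    if not isinstance(text, str) or not text.strip():
        raise AlterationParseError(text, "empty input")
    tokens = [t.strip() for t in text.strip().split(":")]
    if any(not t for t in tokens):
        raise AlterationParseError(text, "empty token between ':' separators")
    if len(tokens) > 3:
        raise AlterationParseError(text, f"too many ':' separated tokens ({len(tokens)})")

    kind: AlterationKind | None = None
    if len(tokens) > 1 and tokens[-1].lower() in _KIND_TOKENS:
        kind = AlterationKind(tokens[-1].lower())
        tokens = tokens[:-1]

    gene = tokens[0]
    detail = tokens[1] if len(tokens) > 1 else ""
    if len(tokens) > 2:
        raise AlterationParseError(text, f"unrecognised trailing token {tokens[2]!r}")

    if _FUSION_RE.match(gene):
        if kind is None:
            kind = AlterationKind.FUSION
        if kind is AlterationKind.FUSION:
            if detail and detail != gene:
                raise AlterationParseError(text, f"conflicting fusion detail {detail!r}")
            detail = gene
    elif not _GENE_RE.match(gene):
        raise AlterationParseError(text, f"bad gene token {gene!r}")

    if kind is None:
        kind = AlterationKind.SNV
    if kind is AlterationKind.FUSION and not _FUSION_RE.match(detail):
        raise AlterationParseError(text, f"fusion requires two partners, got {detail!r}")
    return Alteration(gene=gene, kind=kind, detail=detail)


def format_alteration(a: Alteration) -> str:
    """Serialise to the grammar accepted by :func:`parse_alteration` (round-trips)."""
    if a.kind is AlterationKind.FUSION:
        return f"{a.detail}:fusion"
    out = a.gene
    if a.detail:
        out += f":{a.detail}"
    if a.kind is not AlterationKind.SNV:
        out += f":{a.kind.value}"
    return out


def parse_alteration_list(cell: str) -> list[Alteration]:
    """Parse a semicolon-joined alteration cell; blank cells mean no alterations."""
    cell = (cell or "").strip()
    if not cell:
        return []
    return [parse_alteration(tok) for tok in cell.split(";") if tok.strip()]


def format_alteration_list(alterations: Iterable[Alteration]) -> str:
    return ";".join(format_alteration(a) for a in alterations)


def filter_common_variants(
    alterations: Sequence[Alteration],
    threshold: float = COMMON_VARIANT_THRESHOLD,
) -> list[Alteration]:
    """Drop variants whose known population frequency exceeds ``threshold``.

    Variants common in population databases (frequency strictly above 0.1% by
    default) are germline polymorphisms, not somatic drivers, and are removed
    before scoring.  Unknown frequency is retained: only variants *known* to
    be common are filtered.  Order is preserved; the operation is idempotent.
    """
    if not (0.0 <= threshold <= 1.0):
        raise DomainError(f"threshold must be in [0, 1], got {threshold}")
    return [
        a
        for a in alterations
        if a.population_frequency is None or a.population_frequency <= threshold
    ]


@dataclass(frozen=True)
class TierMap:
    """Deterministic (gene, kind, detail) → risk-tier partition."""

    high_risk_variants: frozenset[tuple[str, str]] = frozenset({("BRAF", "V600E")})
    high_risk_genes: frozenset[str] = frozenset({"TERT"})
    all_fusions_high_risk: bool = True
    ras_like_genes: frozenset[str] = frozenset(RAS_FAMILY)
    ras_like_variants: frozenset[tuple[str, str]] = frozenset({("BRAF", "K601E")})


DEFAULT_TIER_MAP = TierMap()


def assign_tier(a: Alteration, tier_map: TierMap = DEFAULT_TIER_MAP) -> RiskTier:
    """Risk tier of one alteration under a fixed tier map (pure function)."""
    if tier_map.all_fusions_high_risk and a.kind is AlterationKind.FUSION:
        return RiskTier.HIGH_RISK
    if (a.gene, a.detail) in tier_map.high_risk_variants or a.gene in tier_map.high_risk_genes:
        return RiskTier.HIGH_RISK
    if (a.gene, a.detail) in tier_map.ras_like_variants or a.gene in tier_map.ras_like_genes:
        return RiskTier.RAS_LIKE
    return RiskTier.OTHER


# ---------------------------------------------------------------------------
# Weight table


_WILDCARD = "*"


@dataclass(frozen=True)
class WeightTable:
    """Per-alteration percentage weights feeding the genomic classifier.

    Lookup is total and most-specific-first:

    1. exact ``(gene, detail)``
    2. ``(gene, kind)``
    3. ``gene`` alone
    4. wildcard ``(*, kind)`` (lets e.g. every fusion share one weight)
    5. ``default_weight``

    so V600E and K601E can carry different weights on the same gene.
    All weights are percentages in [0, 100].
    """

    by_variant: dict[tuple[str, str], float] = field(default_factory=dict)
    by_gene_kind: dict[tuple[str, AlterationKind], float] = field(default_factory=dict)
    by_gene: dict[str, float] = field(default_factory=dict)
    by_kind: dict[AlterationKind, float] = field(default_factory=dict)
    default_weight: float = 20.0
    combination_rule: str = "saturating_sum"

    def __post_init__(self):
        for w in (
            *self.by_variant.values(),
            *self.by_gene_kind.values(),
            *self.by_gene.values(),
            *self.by_kind.values(),
            self.default_weight,
        ):
            if not (0.0 <= float(w) <= 100.0):
                raise DomainError(f"weights must be in [0, 100], got {w}")
        if self.combination_rule not in ("saturating_sum", "noisy_or"):
            raise DomainError(f"unknown combination rule {self.combination_rule!r}")

    def lookup(self, a: Alteration) -> float:
        if (a.gene, a.detail) in self.by_variant:
            return self.by_variant[(a.gene, a.detail)]
        if (a.gene, a.kind) in self.by_gene_kind:
            return self.by_gene_kind[(a.gene, a.kind)]
        if a.gene in self.by_gene:
            return self.by_gene[a.gene]
        if a.kind in self.by_kind:
            return self.by_kind[a.kind]
        return self.default_weight


#: Default weights.  The per-alteration percentages behind the published
#: classifier are proprietary and unpublished, so these are this package's
#: own documented stand-in, chosen to reproduce the qualitative call
#: structure of the risk tiers: any high-risk alteration alone clears the
#: 70% positivity threshold; a RAS-like alteration alone does not.
DEFAULT_WEIGHT_TABLE = WeightTable(
    by_variant={("BRAF", "V600E"): 95.0, ("BRAF", "K601E"): 55.0},
    by_gene={"TERT": 90.0, "NRAS": 60.0, "HRAS": 60.0, "KRAS": 60.0},
    by_kind={AlterationKind.FUSION: 90.0, AlterationKind.EXPRESSION: 75.0},
    default_weight=20.0,
)


def read_weight_table(
    path: str | Path,
    default_weight: float = 20.0,
    combination_rule: str = "saturating_sum",
) -> WeightTable:
    """Read a weight table from TSV with columns gene, kind, detail, weight.

    ``#`` starts a comment line.  Empty kind/detail cells mean "any";
    gene ``*`` with a kind defines a kind-wide weight; gene ``*`` alone sets
    the default weight.
    """
    by_variant: dict[tuple[str, str], float] = {}
    by_gene_kind: dict[tuple[str, AlterationKind], float] = {}
    by_gene: dict[str, float] = {}
    by_kind: dict[AlterationKind, float] = {}
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if header is None:
            header = [h.strip().lower() for h in fields]
            required = {"gene", "kind", "detail", "weight"}
            if not required.issubset(header):
                raise LoadError(
                    f"weight table must have columns {sorted(required)}, got {header}",
                    row=lineno,
                )
            continue
        row = dict(zip(header, (f.strip() for f in fields)))
        gene = row.get("gene", "")
        kind_s = row.get("kind", "")
        detail = row.get("detail", "")
        try:
            weight = float(row["weight"])
        except (KeyError, ValueError):
            raise LoadError("non-numeric weight", row=lineno, column="weight") from None
        if not (0.0 <= weight <= 100.0):
            raise LoadError(f"weight {weight} outside [0, 100]", row=lineno, column="weight")
        kind = None
        if kind_s:
            try:
                kind = AlterationKind(kind_s.lower())
            except ValueError:
                raise LoadError(f"unknown kind {kind_s!r}", row=lineno, column="kind") from None
        if gene == _WILDCARD:
            if kind is not None:
                by_kind[kind] = weight
            else:
                default_weight = weight
        elif detail:
            by_variant[(gene, detail)] = weight
        elif kind is not None:
            by_gene_kind[(gene, kind)] = weight
        elif gene:
            by_gene[gene] = weight
        else:
            raise LoadError("row has neither gene nor wildcard", row=lineno, column="gene")
    return WeightTable(
        by_variant=by_variant,
        by_gene_kind=by_gene_kind,
        by_gene=by_gene,
        by_kind=by_kind,
        default_weight=default_weight,
        combination_rule=combination_rule,
    )


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    path = Path(path)
    rows = ["gene\tkind\tdetail\tweight"]
    for (gene, detail), w in sorted(table.by_variant.items()):
        rows.append(f"{gene}\t\t{detail}\t{w:g}")
    for (gene, kind), w in sorted(table.by_gene_kind.items()):
        rows.append(f"{gene}\t{kind.value}\t\t{w:g}")
    for gene, w in sorted(table.by_gene.items()):
        rows.append(f"{gene}\t\t\t{w:g}")
    for kind, w in sorted(table.by_kind.items(), key=lambda kv: kv[0].value):
        rows.append(f"{_WILDCARD}\t{kind.value}\t\t{w:g}")
    rows.append(f"{_WILDCARD}\t\t\t{table.default_weight:g}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_vcf_alterations(
    path: str | Path,
    frequency_keys: Sequence[str] = ("POP_AF", "AF"),
) -> list[Alteration]:
    """Map SNV/indel records of a VCF (v4.2) to alterations.

    Gene and protein change are taken from the first entry of an ANN-style
    INFO annotation (``ANN=Allele|Annotation|...|Gene|...|HGVS.p``, SnpEff
    layout); the population frequency from the first INFO key present among
    ``frequency_keys``.  Fusions and expression flags do not travel in VCF
    and enter only via the tabular path.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    out: list[Alteration] = []
    for rec in VCF(str(path)):
        ann = rec.INFO.get("ANN")
        if ann is None:
            continue
        first = str(ann).split(",")[0].split("|")
        gene = first[3] if len(first) > 3 and first[3] else None
        if gene is None:
            continue
        hgvs_p = first[10] if len(first) > 10 else ""
        detail = hgvs_p.removeprefix("p.")
        ref, alts = rec.REF, rec.ALT or [""]
        kind = (
            AlterationKind.SNV
            if len(ref) == 1 and all(len(a) == 1 for a in alts)
            else AlterationKind.INDEL
        )
        freq = None
        for key in frequency_keys:
            val = rec.INFO.get(key)
            if val is not None:
                freq = float(val[0] if isinstance(val, tuple) else val)
                break
        out.append(Alteration(gene=gene, kind=kind, detail=detail, population_frequency=freq))
    return out
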