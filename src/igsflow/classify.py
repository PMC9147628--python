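"""Variant classification into specific / local / ambiguous classes.

Every retained amplicon variant is assigned exactly one class from its
cross-sample abundance pattern:

* ``specific:<species>`` — near-exclusive (> tau of its reads, default
  99.95%) to one species and found in two or more of that species' samples,
  or the species has a single sample in the dataset;
* ``local:<sample>`` — near-exclusive to one species but seen in only one
  of that species' several samples, so not safely attributable to the
  species as a whole;
* ``ambiguous:<category>`` — genuinely shared between species.  Categories
  are evaluated in a fixed precedence order driven by the species role
  flags of the manifest: shared with an outgroup (``sect_melanium``), shared
  between the tricolor role and the rest of the complex (``gr_tricolor``),
  shared between the arvensis role and the kitaibeliana/hymettia roles
  (``gr_arvensis``), and shared only within the kitaibeliana/hymettia pair
  (``kit_hym``).

The exclusivity threshold tau compares read-abundance share, not
presence/absence: a single stray read (e.g. index bleed-through or an
unflagged chimera fragment) must not flip a class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IgsflowError
from .preprocess import VariantTable
from .seqio import SampleManifest

DEFAULT_TAU = 0.9995


class Kind(str, Enum):
    SPECIFIC = "specific"
    LOCAL = "local"
    AMBIGUOUS = "ambiguous"


class AmbiguousCategory(str, Enum):
    SECT_MELANIUM = "sect_melanium"
    GR_TRICOLOR = "gr_tricolor"
    GR_ARVENSIS = "gr_arvensis"
    KIT_HYM = "kit_hym"


@dataclass(frozen=True)
class ClassLabel:
    """One variant's class: kind plus the detail naming it."""

    kind: Kind
    detail: str

    def __str__(self) -> str:
        return f"{self.kind.value}:{self.detail}"

    @property
    def category(self) -> str:
        """The composition category this label aggregates into.

        Species-specific classes stay distinct per species (as the study's
        per-species 'specific' classes do); local classes pool to a single
        'local' category; ambiguous classes keep their category name.
        """
        if self.kind is Kind.SPECIFIC:
            return f"specific:{self.detail}"
        if self.kind is Kind.LOCAL:
            return "local"
        return f"ambiguous:{self.detail}"

    @classmethod
    def parse(cls, text: str) -> "ClassLabel":
        kind, _, detail = text.partition(":")
        return cls(kind=Kind(kind), detail=detail)


def species_share(
    row: np.ndarray, samples: Sequence[str], manifest: SampleManifest
) -> dict[str, float]:
    """Fraction of a variant's reads contributed by each species."""
    row = np.asarray(row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise IgsflowError("species_share of an all-zero abundance row")
    shares: dict[str, float] = {}
    for count, sample in zip(row, samples):
        if count > 0:
            sp = manifest.species_of(sample)
            shares[sp] = shares.get(sp, 0.0) + count
    return {sp: c / total for sp, c in shares.items()}


def _ambiguous_category(
    sharing_species: set[str], manifest: SampleManifest
) -> AmbiguousCategory:
    roles = [manifest.role(sp) for sp in sharing_species]
    any_outgroup = any(r.group == "outgroup" for r in roles)
    any_complex = any(r.group == "complex_member" for r in roles)
    has_tricolor = any(r.is_tricolor for r in roles)
    has_arvensis = any(r.is_arvensis for r in roles)
    has_kit_hym = any(r.is_kit_or_hym for r in roles)
    if any_outgroup and any_complex:
        return AmbiguousCategory.SECT_MELANIUM
    if has_tricolor and (has_arvensis or has_kit_hym):
        return AmbiguousCategory.GR_TRICOLOR
    if has_arvensis and has_kit_hym:
        return AmbiguousCategory.GR_ARVENSIS
    if len(sharing_species) >= 2 and all(r.is_kit_or_hym for r in roles):
        return AmbiguousCategory.KIT_HYM
    warnings.warn(
        f"sharing set {sorted(sharing_species)} matches no ambiguous-class "
        "rule; falling back to sect_melanium",
        stacklevel=3,
    )
    return AmbiguousCategory.SECT_MELANIUM


def assign_class(
    row: np.ndarray,
    samples: Sequence[str],
    manifest: SampleManifest,
    tau: float = DEFAULT_TAU,
) -> ClassLabel:
    """Assign one variant its class from its per-sample abundance row."""
    shares = species_share(row, samples, manifest)
    top_species, top_share = max(shares.items(), key=lambda kv: (kv[1], kv[0]))
    if top_share > tau:
        present = [
            s
            for s, c in zip(samples, np.asarray(row))
            if c > 0 and manifest.species_of(s) == top_species
        ]
        dataset_samples = manifest.samples_of(top_species)
        if len(dataset_samples) == 1 or len(present) >= 2:
            return ClassLabel(Kind.SPECIFIC, top_species)
        return ClassLabel(Kind.LOCAL, present[0])
    return ClassLabel(
        Kind.AMBIGUOUS, _ambiguous_category(set(shares), manifest).value
    )


def assign_all(
    table: VariantTable, manifest: SampleManifest, tau: float = DEFAULT_TAU
) -> list[ClassLabel]:
    return [
        assign_class(table.counts[i], table.samples, manifest, tau=tau)
        for i in range(table.n_variants)
    ]


@dataclass
class ClassComposition:
    sample_id: str
    proportions: dict[str, float]  # category -> fraction of retained reads


def compose(
    table: VariantTable,
    labels: Sequence[ClassLabel],
    manifest: SampleManifest,
    weight: str = "abundance",
) -> list[ClassComposition]:
    """Per-sample class composition.

    ``weight='abundance'`` (default) weights each category by the sample's
    read counts over its variants; ``weight='variants'`` counts each variant
    once — a sensitivity check, not the headline statistic.  Samples with
    zero retained abundance are reported via a warning and excluded.
    """
    if len(labels) != table.n_variants:
        raise IgsflowError("one label per variant required")
    if weight not in ("abundance", "variants"):
        raise ValueError("weight must be 'abundance' or 'variants'")
    out: list[ClassComposition] = []
    for j, sample in enumerate(table.samples):
        col = table.counts[:, j]
        if weight == "variants":
            col = (col > 0).astype(np.int64)
        total = int(col.sum())
        if total == 0:
            warnings.warn(f"sample {sample!r} has zero retained abundance; excluded")
            continue
        props: dict[str, float] = {}
        for i, label in enumerate(labels):
            if col[i]:
                cat = label.category
                props[cat] = props.get(cat, 0.0) + col[i] / total
        out.append(ClassComposition(sample_id=sample, proportions=props))
    return out


def composition_frame(compositions: Sequence[ClassComposition]) -> pd.DataFrame:
    """Sample x category proportion matrix (absent categories are 0)."""
    cats = sorted({c for comp in compositions for c in comp.proportions})
    data = [
        [comp.proportions.get(c, 0.0) for c in cats] for comp in compositions
    ]
    return pd.DataFrame(data, index=[c.sample_id for c in compositions], columns=cats)


def write_labels_tsv(
    table: VariantTable, labels: Sequence[ClassLabel], path
) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tkind\tdetail\n")
        for i, label in enumerate(labels):
            fh.write(f"{table.variant_id(i)}\t{label.kind.value}\t{label.detail}\n")
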