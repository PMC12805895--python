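"""The declared, countable feature schema.

The evidence table has a fixed column order: a block of 23 quantitative
track statistics, one Boolean column per ReMap regulator, one per JASPAR
regulator, one SVD component per k-mer size, then ``ss_mfe`` and ``length``.
With the published configuration (549 ReMap regulators, 146 JASPAR
regulators, k = 3..12) the schema has 25 + 549 + 146 + 10 = 730 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

#: The 23 quantitative track-statistic columns, in declared order.
QUANTITATIVE_FEATURES: tuple[str, ...] = (
    "mean_gc",
    "cov_tfbs",
    "max_tfbs",
    "cov_remap",
    "cov_tss_plus",
    "max_tss_plus",
    "sum_tss_plus",
    "cov_tss_minus",
    "min_tss_minus",
    "sum_tss_minus",
    "cov_s2_pol2",
    "sum_s2_pol2",
    "max_s2_pol2",
    "cov_h3k4me3",
    "mean_h3k4me3",
    "sum_h3k4me3",
    "cov_epdnew",
    "mean_pcons27",
    "std_pcons27",
    "sum_pcons27",
    "mean_phylocons124",
    "std_phylocons124",
    "sum_phylocons124",
)


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names for the evidence matrix."""

    v_remap: tuple[str, ...]
    v_jaspar: tuple[str, ...]
    k_range: tuple[int, ...]
    columns: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        cols = list(QUANTITATIVE_FEATURES)
        cols += [f"remap_{name}" for name in self.v_remap]
        cols += [f"tfbs_{name}" for name in self.v_jaspar]
        cols += [f"{k}mer_SVD1" for k in self.k_range]
        cols += ["ss_mfe", "length"]
        if len(set(cols)) != len(cols):
            raise SchemaError("duplicate feature names in schema")
        object.__setattr__(self, "columns", tuple(cols))

    def __len__(self) -> int:
        return len(self.columns)

    def fingerprint(self) -> str:
        """Stable digest of the column order, stored with trained models."""
        import hashlib

        h = hashlib.sha256("\n".join(self.columns).encode())
        return h.hexdigest()[:16]


def build_schema(
    v_remap: Sequence[str],
    v_jaspar: Sequence[str],
    k_range: Sequence[int],
) -> FeatureSchema:
    """Build the ordered schema from regulator vocabularies and k-mer sizes.

    Regulator blocks are sorted by name; the k-mer block is sorted ascending.
    Total column count is always ``25 + |v_remap| + |v_jaspar| + |k_range|``.
    """
    if not k_range:
        raise SchemaError("k_range must be non-empty")
    ks = tuple(sorted(int(k) for k in k_range))
    if ks[0] < 1:
        raise SchemaError("every k must be >= 1")
    if len(set(ks)) != len(ks):
        raise SchemaError("duplicate k in k_range")
    for name, vocab in (("v_remap", v_remap), ("v_jaspar", v_jaspar)):
        if len(set(vocab)) != len(vocab):
            dupes = sorted({v for v in vocab if list(vocab).count(v) > 1})
            raise SchemaError(f"duplicate regulator name(s) in {name}: {dupes}")
    return FeatureSchema(
        v_remap=tuple(sorted(v_remap)),
        v_jaspar=tuple(sorted(v_jaspar)),
        k_range=ks,
    )
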