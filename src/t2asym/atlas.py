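"""Region atlas: label ids/names with contralateral pair structure.

The analysis treats a brain segmentation as a set of mirrored left/right
region pairs plus a few midline structures with no contralateral
counterpart. The full preset mirrors an 83-region whole-brain
parcellation: 40 left/right pairs and 3 unpaired midline regions
(brainstem, corpus callosum, third ventricle).
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Pair names for the full 83-region layout. The handful of structures the
# downstream analysis talks about by name come first; the rest are generic.
_NAMED_PAIRS = [
    "hippocampus",
    "amygdala",
    "superior_frontal_gyrus",
    "lateral_ventricle_temporal_horn",
    "subcallosal_area",
    "cerebellum",
    "insula",
    "putamen",
    "cingulate_gyrus_posterior",
    "anterior_orbital_gyrus",
    "lateral_occipitotemporal_gyrus",
]
_FULL_UNPAIRED = ["brainstem", "corpus_callosum", "third_ventricle"]


@dataclass
class RegionAtlas:
    """Labels, names and contralateral pairing of a segmentation.

    Attributes
    ----------
    regions : dict[int, str]
        Label id -> region name. Paired regions carry ``_l`` / ``_r``
        suffixes on a shared stem.
    pairs : list[tuple[int, int]]
        (left label, right label) per contralateral pair.
    unpaired : list[int]
        Labels of midline regions with no counterpart.
    """

    regions: dict = field(default_factory=dict)
    pairs: list = field(default_factory=list)
    unpaired: list = field(default_factory=list)

    def __post_init__(self):
        seen = []
        for l, r in self.pairs:
            seen += [l, r]
        seen += list(self.unpaired)
        if sorted(seen) != sorted(self.regions):
            raise ValueError("every label must appear in exactly one pair or in unpaired")
        if len(set(seen)) != len(seen):
            raise ValueError("labels may not repeat across pairs/unpaired")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def pair_name(self, left_label: int) -> str:
        """Stem name shared by a pair, derived from the left member."""
        name = self.regions[left_label]
        return name[:-2] if name.endswith("_l") else name

    @property
    def pair_names(self) -> list:
        return [self.pair_name(l) for l, _ in self.pairs]


def make_atlas(n_pairs: int, n_midline: int) -> RegionAtlas:
    """Atlas with ``2*n_pairs + n_midline`` labels.

    Left members get odd labels 1, 3, 5, ...; their right mirrors the next
    even label; midline regions follow. Names reuse the canonical pair
    names where available.
    """
    regions, pairs = {}, []
    for i in range(n_pairs):
        stem = _NAMED_PAIRS[i] if i < len(_NAMED_PAIRS) else f"region_{i + 1:02d}"
        l, r = 2 * i + 1, 2 * i + 2
        regions[l] = f"{stem}_l"
        regions[r] = f"{stem}_r"
        pairs.append((l, r))
    unpaired = []
    for j in range(n_midline):
        lab = 2 * n_pairs + 1 + j
        name = _FULL_UNPAIRED[j] if j < len(_FULL_UNPAIRED) else f"midline_{j + 1}"
        regions[lab] = name
        unpaired.append(lab)
    return RegionAtlas(regions, pairs, unpaired)


def full_atlas() -> RegionAtlas:
    """The full 83-region layout: 40 contralateral pairs + 3 midline regions."""
    return make_atlas(40, 3)
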