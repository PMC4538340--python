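"""Small bundled datasets.

* The published top-10 validation table for the PXR herbal-ingredient
  screen: the ten best-ranked candidate agonists from the consensus list,
  each flagged for whether a herb containing it has a reported herb-drug
  interaction.  Six of ten are flagged, giving the headline full-depth
  detection rate of 0.6.
* The five-feature PXR template pharmacophore.  Only the feature-type
  signature of that model is public; the bundled geometry is a synthetic
  placeholder (see the JSON's comment field) so the file demonstrates the
  engine, not the original model.
"""

from __future__ import annotations

from importlib import resources

from .pharmacophore import PharmacophoreModel, load_model
from .rank_core import RankedList

__all__ = ["TOP10_PXR_SCREEN", "top10_validation", "pxr_template_model"]

# (rank, ingredient, reported herb-drug interaction)
TOP10_PXR_SCREEN: tuple[tuple[int, str, bool], ...] = (
    (1, "Sophoraflavoside IV", True),
    (2, "Hesperidin", True),
    (3, "Sennoside C&D", False),
    (4, "Ginsenosides Rgl", True),
    (5, "Chlorophy II", False),
    (6, "Solanine", True),
    (7, "Senegenic acid", False),
    (8, "Sophoraflavoside III", True),
    (9, "Phellanmurin", True),
    (10, "Torulosic acid", False),
)


def top10_validation() -> tuple[RankedList, frozenset[str]]:
    """The top-10 consensus ranking and its positive-label set."""
    ordered = sorted(TOP10_PXR_SCREEN)
    ranking = RankedList(
        name="pxr_top10", items=tuple(name for _, name, _ in ordered)
    )
    positives = frozenset(name for _, name, flag in ordered if flag)
    return ranking, positives


def pxr_template_model() -> PharmacophoreModel:
    """Load the bundled (synthetic-geometry) five-feature template."""
    ref = resources.files("dockrank") / "data" / "pxr_template_synthetic.json"
    with resources.as_file(ref) as path:
        return load_model(path)
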