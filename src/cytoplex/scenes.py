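"""Bundled study scenes: the synthetic conditions under which the package
is exercised and validated.

Each builder returns a seeded :class:`~cytoplex.synth.SceneSpec` (and a
matching :class:`~cytoplex.core.TypingSchema` where relevant).  Sizes and
noise levels are fixed design choices, documented in the methods note:

* ``demo`` — an eight-lineage T-cell/stroma-style panel, ~3,000 cells,
  three epithelial (tumour) niches over stromal scatter; high separation
  (log-normal signal median ≈ 12 x background), no attenuation.  Used for
  end-to-end typing and compartment densities.
* ``tcell`` — a four-lineage T-cell panel for cutoff optimisation, with
  the dominant CD3+CD4+ / CD3+CD8a+ populations planted and no rare
  combinations.
* ``confidence`` — a vimentin-family panel in which 20% of cells carry a
  0.2 attenuation of their positive markers (planted low-confidence
  cells); the excluded-lineage perturbation flips their labels, so
  confidence classification can be scored against the planted flags.
* ``barrier`` — a central tumour niche, CD8 T cells scattered outside,
  and (optionally) a fibroblast annulus ringing the tumour: the paired
  scenes differ only in whether the fibroblasts form the ring or are
  scattered, for barrier-score contrasts.
"""

from __future__ import annotations

from .core import Lineage, Perturbation, TypingSchema
from .synth import Annulus, Blob, PopulationSpec, SceneSpec

# -- eight-lineage demo panel ------------------------------------------------

DEMO_MARKERS = ("Vimentin", "CD31", "panCK", "aSMA", "CD45", "CD3", "CD4", "CD8a")

DEMO_LINEAGES = (
    Lineage("Vimentin+ cells", ("Vimentin",)),
    Lineage("Endothelial cells", ("Vimentin", "CD31")),
    Lineage("Epithelial cells", ("panCK",)),
    Lineage("aSMA+ cells", ("Vimentin", "aSMA")),
    Lineage("CD4 T cells", ("CD45", "CD3", "CD4")),
    Lineage("CD8 T cells", ("CD45", "CD3", "CD8a")),
    Lineage("T cells - Other", ("CD45", "CD3")),
    Lineage("Leukocytes - Other", ("CD45",)),
)


def demo_schema() -> TypingSchema:
    """Eight major lineages with a shared-marker hierarchy (CD45 ⊂ CD45/CD3
    ⊂ T subsets; vimentin shared by three stromal lineages); perturbation
    excludes the vimentin-only lineage and drops vimentin."""
    return TypingSchema(
        markers=DEMO_MARKERS,
        lineages=DEMO_LINEAGES,
        perturbation=Perturbation("Vimentin+ cells", ("Vimentin",)),
    )


def demo_scene(seed: int = 0, lowconf_fraction: float = 0.0,
               attenuation: float = 1.0) -> tuple[SceneSpec, TypingSchema]:
    """~3,000 cells over a 1,000 µm square: three epithelial niches
    (r = 120 µm, 250 cells each) plus uniform scatter of all lineages."""
    def pop(name, count, markers):
        return PopulationSpec(name, count, markers,
                              lowconf_fraction=lowconf_fraction,
                              attenuation=attenuation)

    populations = (
        pop("Vimentin+ cells", 150, ("Vimentin",)),
        pop("Endothelial cells", 300, ("Vimentin", "CD31")),
        pop("Epithelial cells", 900, ("panCK",)),
        pop("aSMA+ cells", 300, ("Vimentin", "aSMA")),
        pop("CD4 T cells", 450, ("CD45", "CD3", "CD4")),
        pop("CD8 T cells", 400, ("CD45", "CD3", "CD8a")),
        pop("T cells - Other", 250, ("CD45", "CD3")),
        pop("Leukocytes - Other", 250, ("CD45",)),
    )
    blobs = (
        Blob((250.0, 250.0), 120.0, "Epithelial cells", 250),
        Blob((720.0, 300.0), 120.0, "Epithelial cells", 250),
        Blob((480.0, 740.0), 120.0, "Epithelial cells", 250),
    )
    spec = SceneSpec(markers=DEMO_MARKERS, populations=populations,
                     blobs=blobs, seed=seed)
    return spec, demo_schema()


# -- T-cell cutoff panel -----------------------------------------------------

TCELL_MARKERS = ("CD45", "CD3", "CD4", "CD8a", "panCK", "CD31")


def tcell_schema() -> TypingSchema:
    return TypingSchema(
        markers=TCELL_MARKERS,
        lineages=(
            Lineage("CD4 T cells", ("CD45", "CD3", "CD4")),
            Lineage("CD8 T cells", ("CD45", "CD3", "CD8a")),
            Lineage("T cells - Other", ("CD45", "CD3")),
            Lineage("Leukocytes - Other", ("CD45",)),
            Lineage("Epithelial cells", ("panCK",)),
            Lineage("Endothelial cells", ("CD31",)),
        ),
        perturbation=Perturbation("CD4 T cells", ("CD4",)),
    )


def tcell_scene(seed: int = 0) -> tuple[SceneSpec, TypingSchema]:
    """Dominant CD3+CD4+ and CD3+CD8a+ populations planted with clean
    separation and no rare reference-marker combinations; epithelial and
    endothelial context populations give the ubiquitous leukocyte markers
    (CD45, CD3) the between-cluster contrast the rank statistic needs."""
    populations = (
        PopulationSpec("CD4 T cells", 600, ("CD45", "CD3", "CD4")),
        PopulationSpec("CD8 T cells", 500, ("CD45", "CD3", "CD8a")),
        PopulationSpec("T cells - Other", 300, ("CD45", "CD3")),
        PopulationSpec("Leukocytes - Other", 400, ("CD45",)),
        PopulationSpec("Epithelial cells", 800, ("panCK",)),
        PopulationSpec("Endothelial cells", 400, ("CD31",)),
    )
    return SceneSpec(markers=TCELL_MARKERS, populations=populations,
                     seed=seed), tcell_schema()


# -- confidence / attenuation panel -------------------------------------------

CONFIDENCE_MARKERS = ("Vimentin", "CD31", "aSMA", "CD45")


def confidence_schema() -> TypingSchema:
    return TypingSchema(
        markers=CONFIDENCE_MARKERS,
        lineages=(
            Lineage("Vimentin+ cells", ("Vimentin",)),
            Lineage("Endothelial cells", ("Vimentin", "CD31")),
            Lineage("aSMA+ cells", ("Vimentin", "aSMA")),
            Lineage("Leukocytes - Other", ("CD45",)),
        ),
        reference_markers=CONFIDENCE_MARKERS,
        population_criteria={"dominant": ({"Vimentin": "+"},), "rare": ()},
        perturbation=Perturbation("Vimentin+ cells", ("Vimentin",)),
    )


def confidence_scene(seed: int = 0, lowconf_fraction: float = 0.2,
                     attenuation: float = 0.2) -> tuple[SceneSpec, TypingSchema]:
    """3,000 cells, 20% planted low-confidence at 0.2 attenuation.

    Attenuated cells of the vimentin-sharing lineages gravitate to the
    weakest definition (the vimentin-only lineage) under the complete model
    and are forced to flip when it is excluded, so planted low-confidence
    status is recoverable from the perturbation flags."""
    def pop(name, count, markers):
        return PopulationSpec(name, count, markers,
                              lowconf_fraction=lowconf_fraction,
                              attenuation=attenuation)

    populations = (
        pop("Vimentin+ cells", 300, ("Vimentin",)),
        pop("Endothelial cells", 900, ("Vimentin", "CD31")),
        pop("aSMA+ cells", 900, ("Vimentin", "aSMA")),
        pop("Leukocytes - Other", 900, ("CD45",)),
    )
    return SceneSpec(markers=CONFIDENCE_MARKERS, populations=populations,
                     seed=seed), confidence_schema()


# -- barrier geometry ----------------------------------------------------------

def barrier_scene(seed: int = 0, with_annulus: bool = True) -> SceneSpec:
    """A tumour niche (r = 150 µm) at the centre of a 1,000 µm image, CD8 T
    cells scattered outside, and 350 fibroblasts either ringing the tumour
    (annulus 150–190 µm) or scattered uniformly — the paired contrast for
    barrier scoring.  Counts are identical in both variants."""
    populations = (
        PopulationSpec("Tumour", 600, ("panCK",)),
        PopulationSpec("CD8 T cells", 400, ("CD8a",)),
        PopulationSpec("Fibroblasts", 350, ("aSMA",)),
        PopulationSpec("Other", 650, ()),
    )
    blobs = (Blob((500.0, 500.0), 150.0, "Tumour", 600),)
    annulus = Annulus((500.0, 500.0), 150.0, 190.0, "Fibroblasts", 350) \
        if with_annulus else None
    return SceneSpec(markers=("panCK", "CD8a", "aSMA"), populations=populations,
                     blobs=blobs, annulus=annulus, seed=seed)
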