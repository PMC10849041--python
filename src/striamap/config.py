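"""Numeric conventions of the input-mapping analysis.

Every threshold the pipeline uses lives here so that no stage hard-codes a
constant: the 0.5 µm punctum-to-membrane edge rule, the 5 µm cross-channel
cluster threshold, the 10 µm path-distance bins, the proximal/medial/distal
region bounds, and the spine-calibre bounds used by the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis conventions, all distances in micrometres.

    Parameters
    ----------
    edge_threshold
        Maximum clearance between a punctum's surface and the neuron's
        membrane for the punctum to count as a putative input (inclusive).
    cluster_threshold
        Centre-to-centre distance defining a cross-channel cluster.
    bin_width
        Width of the along-dendrite distance histogram bins.
    region_bounds
        ``(proximal_max, medial_max)``: path distance < proximal_max is
        proximal, [proximal_max, medial_max) is medial, >= medial_max distal.
    spine_diameter_bounds
        Calibre range accepted for dendritic spines.
    coloc_threshold_vglut
        Edge-to-edge threshold for VGLUT1 validation colocalization.
    """

    edge_threshold: float = 0.5
    cluster_threshold: float = 5.0
    bin_width: float = 10.0
    region_bounds: tuple[float, float] = (30.0, 100.0)
    spine_diameter_bounds: tuple[float, float] = (0.6, 2.5)
    coloc_threshold_vglut: float = 0.5
    min_punctum_diameter: float = 1.0

    def __post_init__(self) -> None:
        positive = {
            "edge_threshold": self.edge_threshold,
            "cluster_threshold": self.cluster_threshold,
            "bin_width": self.bin_width,
            "coloc_threshold_vglut": self.coloc_threshold_vglut,
            "min_punctum_diameter": self.min_punctum_diameter,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value!r}")
        prox, med = self.region_bounds
        if not (0 < prox < med):
            raise ValueError(
                f"region_bounds must satisfy 0 < proximal_max < medial_max, got {self.region_bounds!r}"
            )
        lo, hi = self.spine_diameter_bounds
        if not (0 < lo < hi):
            raise ValueError(f"spine_diameter_bounds must be increasing and positive, got {self.spine_diameter_bounds!r}")


DEFAULT_CONFIG = AnalysisConfig()
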