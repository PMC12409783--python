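"""Presets for published Visium / ST benchmark datasets.

These presets only carry the analysis parameters (cluster count, feature
filter, HVG count, CNN backend) needed to attempt the published
analyses out-of-band; the datasets themselves (and pretrained CNN
weights) must be downloaded separately, so no preset is exercised by
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DatasetPreset:
    name: str
    k: int                      # annotated cluster count used for evaluation
    source: str                 # where to obtain the data (out-of-band)
    min_frac: float = 0.01      # features detected in >= 1% of spots retained
    n_hvg: int = 2000
    image_backend: str = "vgg16"
    notes: str = ""


PRESETS: dict[str, DatasetPreset] = {
    p.name: p for p in [
        DatasetPreset(
            name="her2-breast", k=6,
            source="ST HER2-positive breast tumor collection (public repository)",
            notes="annotated regions: 6"),
        DatasetPreset(
            name="pdac", k=4,
            source="pancreatic ductal adenocarcinoma ST sample (GEO)",
            notes="paired scRNA-seq available for MIA"),
        DatasetPreset(
            name="dlpfc-151673", k=7,
            source="spatialLIBD (http://spatial.libd.org/spatialLIBD/)",
            notes="human dorsolateral prefrontal cortex, layers + WM"),
        DatasetPreset(
            name="mouse-kidney", k=10,
            source="10x Genomics Datasets website (Visium mouse kidney)",
            notes="19465 genes x 3124 spots"),
    ]
}
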