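"""Canonical synthetic study designs used by the analysis drivers and checks.

Two designs recur throughout the package:

* the *assembly design*: a 100-taxon pool, four DSR groups of five samples
  (levels 1, 4, 5 and 8, whose glucose values are distinct so the gradient
  is informative), richness 30 per sample and 5,000 reads — run either
  neutrally or with habitat filtering at kernel width 0.25 trait-SD;
* the *screen design*: 8 DSR levels x 10 samples with 40 features per
  response shape at signal-to-noise ratio 4 (noise SD = SD of the
  noise-free response over the design, divided by 4).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import SampleMetadata
from .synthetic import (
    SHAPE_NAMES,
    AssemblySpec,
    ShapeSpec,
    generate_response_table,
    generate_study,
)

__all__ = [
    "assembly_design",
    "run_assembly_study",
    "screen_metadata",
    "snr_shape_specs",
    "run_screen_study",
]

ASSEMBLY_DSR_LEVELS = (1, 4, 5, 8)


def assembly_design(mode: str, seed: int) -> AssemblySpec:
    """The 20-sample assembly design (neutral or filtering)."""
    return AssemblySpec(
        mode=mode, n_taxa_pool=100, n_samples_per_group=5,
        dsr_levels=ASSEMBLY_DSR_LEVELS, richness_per_sample=30,
        seq_depth=5000, filter_strength=0.25, seed=seed,
    )


def run_assembly_study(mode: str, seed: int):
    """Generate tree, traits, metadata and OTU table for the assembly design."""
    return generate_study(assembly_design(mode, seed), bm_sd=1.0)


def screen_metadata(n_per_level: int = 10,
                    levels: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
                    ) -> SampleMetadata:
    dsr = sorted(list(levels) * n_per_level)
    ids = [f"S{i + 1:03d}" for i in range(len(dsr))]
    return SampleMetadata(pd.DataFrame({"dsr_level": dsr}, index=ids))


def snr_shape_specs(n_per_shape: int, snr: float = 4.0,
                    amplitude: float = 1.0, vertex: float = 5.0,
                    levels: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
                    ) -> list[ShapeSpec]:
    """One block of specs per shape with noise set by the target SNR.

    SNR is the SD of the noise-free response over the design grid divided
    by the noise SD; flat ("none") features get unit noise.
    """
    grid = np.asarray(levels, dtype=float)
    specs: list[ShapeSpec] = []
    for shape in SHAPE_NAMES:
        base = ShapeSpec(shape, amplitude=amplitude, vertex=vertex)
        signal_sd = float(np.std(base.mean(grid)))
        noise = signal_sd / snr if signal_sd > 0 else 1.0
        specs += [ShapeSpec(shape, amplitude=amplitude, vertex=vertex,
                            noise_sd=noise)] * n_per_shape
    return specs


def run_screen_study(n_per_shape: int, seed: int, snr: float = 4.0):
    """Feature table plus ground-truth labels for the screen design."""
    metadata = screen_metadata()
    specs = snr_shape_specs(n_per_shape, snr=snr)
    features, truth = generate_response_table(metadata, specs, seed=seed)
    return metadata, features, truth
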