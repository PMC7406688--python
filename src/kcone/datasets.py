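"""Bundled example data.

The bundled reconstruction is a SYNTHETIC STAND-IN: a hand-curated
central-metabolism network (glycolysis, pentose phosphate, TCA, amino acid,
one-carbon, glutathione, fatty acid and polyamine chemistry) at the scale
of a medium-size NSCLC reconstruction — 74 internal metabolites and 112
reactions.  It is a structurally realistic instance for exercising the
pipeline, not a transcription of any published network.
"""

from __future__ import annotations

from importlib.resources import files

from .network import MetabolicNetwork, parse_reaction_file

__all__ = ["bundled_reconstruction_text", "load_bundled_reconstruction"]

_RECON = "reconstruction_synthetic_74x112.txt"


def bundled_reconstruction_text() -> str:
    return (files("kcone") / "data" / _RECON).read_text(encoding="utf-8")


def load_bundled_reconstruction() -> MetabolicNetwork:
    """Parse the bundled synthetic stand-in reconstruction (74 x 112)."""
    return parse_reaction_file(bundled_reconstruction_text())
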