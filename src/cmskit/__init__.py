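"""cmskit: CMS4-directed colorectal-cancer transcriptomics.

Subpackages cover the full analysis chain: synthetic cohorts with planted
ground truth (:mod:`cmskit.synthetic`), the kinome/Kd drug-selectivity screen
(:mod:`cmskit.screen`), CMS classification with multi-biopsy aggregation
(:mod:`cmskit.classify`), the statistical primitives (:mod:`cmskit.stats`),
the pre/post phenotype-shift analysis (:mod:`cmskit.shift`), and cohort
stratification with survival (:mod:`cmskit.stratify`).
"""

from importlib import resources

from .io import ExpressionMatrix, read_expression, read_gmt, write_expression, write_gmt

__version__ = "0.1.0"

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "read_gmt",
    "write_expression",
    "write_gmt",
    "bundled_signatures",
]


def bundled_signatures() -> dict[str, list[str]]:
    """The fixture signature gene sets shipped with the package.

    Small illustrative membership lists for the signatures the analyses use
    (4-gene CMS4 test, mesenchymal/CMS4-up, adherens junction, desmosome,
    circulating cell cluster, WNT targets, MYC targets, cell cycle, mTORC1
    TOP targets). Users may substitute full published GMTs; membership is
    data, not code.
    """
    path = resources.files("cmskit").joinpath("data/example_signatures.gmt")
    with resources.as_file(path) as p:
        return read_gmt(p)
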