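"""Bundled example data.

One small plain-text table ships with the package: the published
shared-locus table for type 2 diabetes versus three sleep traits
(insomnia symptoms, sleep duration, chronotype) — 62 rows covering 58
independent loci at conjFDR < 0.01, with lead-SNP z-scores and p-values
for both traits.  It serves as a worked example of the locus-table
format and as the round-trip fixture for the parser.
"""

from importlib import resources

import pandas as pd

from .pipeline import parse_locus_table

__all__ = ["example_locus_table_path", "load_example_locus_table", "load_example_loci"]

_FILENAME = "shared_loci_t2d_sleep.tsv"


def example_locus_table_path():
    """Filesystem path of the bundled locus table."""
    return resources.files("crosstrait") / "data" / _FILENAME


def load_example_locus_table() -> pd.DataFrame:
    """The bundled locus table as a raw DataFrame (one row per locus x gene)."""
    with resources.as_file(example_locus_table_path()) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def load_example_loci():
    """The bundled locus table parsed into SharedLocus records (58 loci)."""
    with resources.as_file(example_locus_table_path()) as p:
        return parse_locus_table(p)
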