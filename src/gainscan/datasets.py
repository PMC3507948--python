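"""Small reference datasets shipped with the package.

``load_pmf_table`` returns the published MALDI-TOF fingerprint of the
lamprey RPE65 band (centroid/theoretical masses, printed differences,
intensities, peptide ranges and modification forms); the numeric columns
keep their printed precision and the raw strings are preserved alongside,
since the printed decimal count matters when re-deriving the difference
column. ``load_diverged_residues`` returns the seven-residue diagnostic set
that separates authentic RPE65 sequences from other carotenoid oxygenases.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from gainscan.divergence import DiagnosticResidueSet

#: length (residues) of the fingerprinted lamprey RPE65 protein
PMF_PARENT_LENGTH = 537


def _data_path(name: str):
    return resources.files("gainscan").joinpath("data", name)


def load_pmf_table() -> pd.DataFrame:
    """The published peptide-mass-fingerprint table (17 rows).

    Columns: centroid_mass, theoretical_mass, difference, relative_intensity
    (floats); start, end (int); modification (none / pyroGlu-Q /
    oxidation-M / acetyl-Nterm); plus ``*_str`` columns holding the numbers
    exactly as printed.
    """
    with resources.as_file(_data_path("table1_pmf.tsv")) as path:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    df.columns = [
        "centroid_mass",
        "theoretical_mass",
        "difference",
        "relative_intensity",
        "start",
        "end",
        "modification",
    ]
    for col in ("centroid_mass", "theoretical_mass", "difference"):
        df[col + "_str"] = df[col]
        df[col] = df[col].astype(float)
    df["relative_intensity"] = df["relative_intensity"].astype(float)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def load_diverged_residues(reference_id: str = "RPE65") -> DiagnosticResidueSet:
    """The seven type-II diverged residues, numbered on an RPE65 reference."""
    with resources.as_file(_data_path("rpe65_diverged_residues.tsv")) as path:
        return DiagnosticResidueSet.from_tsv(path, reference_id)
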