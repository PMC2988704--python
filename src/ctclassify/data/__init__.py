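"""Bundled reference data.

``glioma30_pergene_params.tsv`` holds the published cross-platform
agreement parameters (Pearson correlation, regression coefficient and
intercept of log expression on −ΔCt) for the 30-gene glioma prognosis
panel, measured between a relative-expression profiling platform and
real-time PCR with UBL5 as the reference gene.  It is the canonical
worked example for the correlation-based gene filter.
"""

from importlib import resources

import pandas as pd

from ..models import PerGeneStat

__all__ = ["load_glioma30_stats"]


def load_glioma30_stats() -> list[PerGeneStat]:
    """Per-gene cross-platform statistics of the 30-gene glioma panel."""
    ref = resources.files(__package__) / "glioma30_pergene_params.tsv"
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    return [
        PerGeneStat(
            gene_id=row["gene"],
            correlation=float(row["correlation"]),
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
        )
        for _, row in frame.iterrows()
    ]
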