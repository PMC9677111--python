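"""Small built-in reference tables.

``reference_marker_table`` holds a published informativeness benchmark for
thirteen polymorphic EST-SSR primers screened on a 24-accession kalmegh
(*Andrographis paniculata*) panel: two bands per primer, all polymorphic,
with per-primer PIC, resolving power, marker index and effective marker
index (QM = 1.0, DC = 0.75, PR = 1.0).  It is used for arithmetic
self-consistency checks of the informativeness formulas; the underlying
raw band matrix is not published, so data-dependent statistics cannot be
recomputed from it.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["reference_marker_table"]

_ROWS = [
    # primer,    TNB, NPB, PP,  PIC,   RP,    EMR, MI,    QM,  QND,  EMI
    ("APSSR1",   2,  2, 100, 0.326, 1.833, 2, 0.653, 1.0, 0.75, 0.490),
    ("APSSR3",   2,  2, 100, 0.345, 1.750, 2, 0.691, 1.0, 0.75, 0.518),
    ("APSSR5",   2,  2, 100, 0.283, 1.583, 2, 0.566, 1.0, 0.75, 0.424),
    ("APSSR6",   2,  2, 100, 0.450, 1.750, 2, 0.899, 1.0, 0.75, 0.674),
    ("APSSR7",   2,  2, 100, 0.149, 1.833, 2, 0.299, 1.0, 0.75, 0.224),
    ("APSSR12",  2,  2, 100, 0.465, 1.500, 2, 0.931, 1.0, 0.75, 0.698),
    ("APSSR14",  2,  2, 100, 0.299, 1.500, 2, 0.597, 1.0, 0.75, 0.448),
    ("APSSR16",  2,  2, 100, 0.352, 2.917, 2, 0.705, 1.0, 0.75, 0.529),
    ("APSSR17",  2,  2, 100, 0.387, 1.417, 2, 0.774, 1.0, 0.75, 0.581),
    ("APSSR18",  2,  2, 100, 0.247, 1.500, 2, 0.493, 1.0, 0.75, 0.370),
    ("APSSR19",  2,  2, 100, 0.247, 0.667, 2, 0.493, 1.0, 0.75, 0.370),
    ("APSSR29",  2,  2, 100, 0.274, 1.833, 2, 0.549, 1.0, 0.75, 0.411),
    ("APSSR33",  2,  2, 100, 0.361, 1.667, 2, 0.722, 1.0, 0.75, 0.542),
]

_AVERAGE = ("Average", 2, 2, 100, 0.322, 1.673, 2, 0.644, 1.0, 0.75, 0.483)

_COLUMNS = ["TNB", "NPB", "PP", "PIC", "RP", "EMR", "MI", "QM", "QND", "EMI"]


def reference_marker_table(include_average: bool = False) -> pd.DataFrame:
    """Benchmark per-primer informativeness values (see module docstring).

    With ``include_average=True`` the published Average row is appended
    as printed (3-decimal rounding included).
    """
    rows = list(_ROWS) + ([_AVERAGE] if include_average else [])
    df = pd.DataFrame([r[1:] for r in rows], index=[r[0] for r in rows],
                      columns=_COLUMNS)
    return df.astype(float)
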