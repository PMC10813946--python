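"""Frequency-table I/O and packaged example datasets.

Two text dialects are accepted:

* a counts CSV with header ``value,count`` — one row per observed value;
* a raw observation file with header ``x`` — one nonnegative integer per
  line, tabulated on load.

Four classic datasets ship with the package: the Prussian horse-kick
fatality counts (von Bortkiewicz, 1898) and a traffic-volume survey at a
T-intersection, each in an original form and an altered form in which a
known number of ones were deliberately re-recorded as zeros to emulate
misclassification.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

from .estimators import Estimate, FrequencyTable, LBComponents


@dataclass(frozen=True)
class Fixture:
    name: str
    table: FrequencyTable
    provenance: str


def _fx(name: str, counts: dict, provenance: str) -> Fixture:
    return Fixture(name=name, table=FrequencyTable.from_pairs(counts), provenance=provenance)


FIXTURES = {
    f.name: f
    for f in [
        _fx(
            "horsekick_original",
            {0: 109, 1: 65, 2: 22, 3: 3, 4: 1, 5: 0},
            "Annual deaths by horse kick in Prussian army corps, 1875-1894 "
            "(von Bortkiewicz, Das Gesetz der kleinen Zahlen, 1898)",
        ),
        _fx(
            "horsekick_altered",
            {0: 129, 1: 45, 2: 22, 3: 3, 4: 1, 5: 0},
            "Horse-kick data with 20 of the 65 ones re-recorded as zeros "
            "to emulate misclassification",
        ),
        _fx(
            "traffic_original",
            {0: 15, 1: 5, 2: 9, 3: 6, 4: 7, 5: 1, 6: 2},
            "Small-car traffic volume at a T-intersection (manual counts)",
        ),
        _fx(
            "traffic_altered",
            {0: 18, 1: 2, 2: 9, 3: 6, 4: 7, 5: 1, 6: 2},
            "Traffic data with 3 of the 5 ones re-recorded as zeros "
            "to emulate misclassification",
        ),
    ]
}


def load_fixture(name: str) -> FrequencyTable:
    """Return a packaged dataset by name (see ``FIXTURES`` for the list)."""
    try:
        return FIXTURES[name].table
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


class CountsFormatError(ValueError):
    """Malformed counts file; message carries the offending line number."""


def _parse_int(text: str, line_no: int, what: str) -> int:
    try:
        value = int(text)
    except ValueError:
        raise CountsFormatError(f"line {line_no}: {what} {text!r} is not an integer") from None
    if value < 0:
        raise CountsFormatError(f"line {line_no}: {what} {text!r} is negative")
    return value


def read_counts(path) -> FrequencyTable:
    """Read a frequency table from a counts CSV or raw observation file.

    The dialect is auto-detected from the header: ``value,count`` for a
    tabulated file, ``x`` for one observation per line.  Duplicate
    values in a counts file are merged by summation.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CountsFormatError("line 1: file is empty (header required)") from None
        header = [h.strip().lower() for h in header]
        if header == ["value", "count"]:
            tally: dict[int, int] = {}
            for line_no, row in enumerate(reader, start=2):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) != 2:
                    raise CountsFormatError(f"line {line_no}: expected 2 fields, got {len(row)}")
                value = _parse_int(row[0].strip(), line_no, "value")
                count = _parse_int(row[1].strip(), line_no, "count")
                tally[value] = tally.get(value, 0) + count
            if not tally:
                raise CountsFormatError("no data rows found")
            return FrequencyTable.from_pairs(tally)
        if header == ["x"]:
            tally = {}
            for line_no, row in enumerate(reader, start=2):
                if not row or not row[0].strip():
                    continue
                if len(row) != 1:
                    raise CountsFormatError(f"line {line_no}: expected 1 field, got {len(row)}")
                value = _parse_int(row[0].strip(), line_no, "observation")
                tally[value] = tally.get(value, 0) + 1
            if not tally:
                raise CountsFormatError("no observations found")
            return FrequencyTable.from_pairs(tally)
        raise CountsFormatError(
            f"line 1: unrecognised header {header!r}; expected 'value,count' or 'x'"
        )


def estimate_to_dict(est: Estimate, components: LBComponents | None = None) -> dict:
    """JSON-ready representation of a fit (matrices row-major)."""
    out = {
        "method": est.method,
        "theta_hat": {"lambda": est.lambda_hat, "phi": est.phi_hat},
        "warnings": list(est.warnings),
    }
    if components is not None:
        out["linear_bayes_components"] = {
            "W": components.w.ravel().tolist(),
            "M": components.m.ravel().tolist(),
            "B": components.b_mat.ravel().tolist(),
            "b": components.b_vec.tolist(),
        }
    return out


def estimate_to_json(est: Estimate, components: LBComponents | None = None) -> str:
    return json.dumps(estimate_to_dict(est, components), indent=2)
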