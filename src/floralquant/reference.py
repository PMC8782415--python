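"""Published reference values for the default model (comparison fixtures).

Loaded once from ``data/reference_tables.json``.  These numbers are used
as declared *inputs* (the published gradient vector feeding the AHP worked
example, the published priority vector feeding its λ/CI stage) and as the
comparison side of the replication diff report.  They are never returned
in place of a computed value without an explicit ``provenance`` marker.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

__all__ = ["reference_tables"]


@lru_cache(maxsize=1)
def reference_tables() -> dict:
    path = resources.files("floralquant.data").joinpath("reference_tables.json")
    return json.loads(path.read_text())
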