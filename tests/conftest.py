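"""Shared fixtures: tiny hand-built graphs with hand-computable answers."""

import io

import pytest

from pangrowth import gfa_io

# Three paths over four unit-length segments realizing the coverage
# histogram h = [h0, 2, 1, 1] with n = 3 ungrouped paths:
#   a is in p1 only, b in p2 only, c in p1 and p2, d in all three.
TINY_GFA = """\
H\tVN:Z:1.1
S\ta\tA
S\tb\tC
S\tc\tG
S\td\tT
L\ta\t+\tc\t+\t0M
L\tc\t+\td\t+\t0M
L\tb\t+\tc\t+\t0M
P\tp1\ta+,c+,d+\t*
P\tp2\tb+,c+,d+\t*
P\tp3\td+\t*
"""

# The explicit per-path node sets of TINY_GFA, for brute-force oracles.
TINY_SETS = [{"a", "c", "d"}, {"b", "c", "d"}, {"d"}]


@pytest.fixture
def tiny_graph() -> gfa_io.PangenomeGraph:
    return gfa_io.parse_gfa(io.StringIO(TINY_GFA))


@pytest.fixture
def tiny_gfa_file(tmp_path):
    path = tmp_path / "tiny.gfa"
    path.write_text(TINY_GFA)
    return path
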