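import io
import textwrap

import pytest

from dielbal import read_topology


TOY_ITP = textwrap.dedent(
    """\
    ; toy two-atom molecule
    [ atomtypes ]
    ; name  mass  charge  ptype  sigma  epsilon
    ha   1.008   0.0  A  0.25  0.10
    oa  15.999   0.0  A  0.30  0.65

    [ moleculetype ]
    TOY  3

    [ atoms ]
    ;  nr type resnr residue atom cgnr charge     mass
       1  ha   1     TOY     H1   1    0.500000   1.008
       2  oa   1     TOY     O1   2   -0.500000  15.999

    [ bonds ]
    ; i  j  func  b0     kb
      1  2  1     0.097  462750.4
    """
)


@pytest.fixture
def toy_itp_text() -> str:
    return TOY_ITP


@pytest.fixture
def toy_topology():
    return read_topology(io.StringIO(TOY_ITP))
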