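import pytest

from rih import Scorecard

# The three worked scorecards whose attribute points are printed in the
# published illustration, in canonical attribute order.
WORKED_EXAMPLES = {
    "innovation_1": [4, 4, 5, 4, 5, 5, 5, 4, 5],
    "innovation_2": [5, 2, 5, 2, 5, 5, 2, 4, 2],
    "innovation_3": [5, 1, None, 2, 4, 1, None, 1, 2],
}


@pytest.fixture
def worked_scorecards() -> dict[str, Scorecard]:
    return {
        name: Scorecard.from_points(name, pts, sources=[3 if p is not None else None for p in pts])
        for name, pts in WORKED_EXAMPLES.items()
    }
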