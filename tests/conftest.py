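import numpy as np
import pytest

from orodiversify.io_model import AreaCoding, TimeTree, TreeNode, read_time_tree


@pytest.fixture
def three_tip_tree(tmp_path):
    """The worked example ((A:1,B:1):1,C:2) with tips at age 0."""
    p = tmp_path / "three.nwk"
    p.write_text("((A:1,B:1):1,C:2);\n")
    return read_time_tree(p)


@pytest.fixture
def zero_cherry():
    """A cherry with zero-length branches (no time for range change)."""
    root = TreeNode(id="root", age=0.0)
    for name in ("A", "B"):
        root.children.append(TreeNode(id=name, age=0.0, parent=root))
    return TimeTree(root)


@pytest.fixture
def two_area_coding_same():
    return AreaCoding(("A", "B"), {"A": frozenset("A"), "B": frozenset("A")})


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
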