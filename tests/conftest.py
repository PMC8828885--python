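import numpy as np
import pytest

from tissuemux.io import ChannelMetadata, ChannelStack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_stack(planes: dict[str, np.ndarray], pixel_size_um: float = 1.0,
               sample_id: str = "test", roles: dict[str, str] | None = None) -> ChannelStack:
    """Build a ChannelStack from named 2-D arrays (test helper)."""
    roles = roles or {}
    names = list(planes)
    pixels = np.stack([np.asarray(planes[n], dtype=np.float32) for n in names], axis=-1)
    channels = [
        ChannelMetadata(n, label=f"tag{i}", index=i, role=roles.get(n, "marker"))
        for i, n in enumerate(names)
    ]
    return ChannelStack(pixels=pixels, channels=channels,
                        pixel_size_um=pixel_size_um, sample_id=sample_id)
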