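import pytest

from foramcensus.samples import CensusSample, SampleMetadata
from foramcensus.taxonomy import TaxonomyScheme


@pytest.fixture(scope="session")
def scheme():
    return TaxonomyScheme.load()


DEFAULT_VALUES = {"g_bulloides": 0.5, "g_ruber_white": 0.3, "n_incompta": 0.2}


def build_sample(sid, name=None, lat=0.0, lon=0.0, values=None, counts=None,
                 count=None, year=2000, lat_precision=4, lon_precision=4,
                 device="Piston", **meta):
    """Construct a processed census sample for dereplication/QC tests."""
    values = dict(DEFAULT_VALUES if values is None else values)
    metadata = SampleMetadata(
        sample_name=(name or sid).upper(), sample_id=sid, device=device,
        latitude=lat, longitude=lon, year=year, count=count,
        **meta)
    return CensusSample(metadata=metadata, original=dict(values),
                        counts=counts, relative=values,
                        lat_precision=lat_precision,
                        lon_precision=lon_precision)


@pytest.fixture
def make_sample():
    return build_sample
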