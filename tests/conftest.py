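"""Shared test configuration: deterministic property testing."""

from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")
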