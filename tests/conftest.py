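from hypothesis import settings

# property tests must reproduce identically in any environment
settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
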