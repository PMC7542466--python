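# No-biology sample configuration: physical transport only.
fixture: no_bio
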