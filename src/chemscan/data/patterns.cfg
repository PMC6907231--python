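# condition-keyword pattern table (key = value, space-separated lists)
time_units = s sec secs min mins h hr hrs hour hours d day days
time_qualitative = overnight
temp_units = °C C K
temp_qualitative = rt r.t. reflux
yield_prefixes = yield yield:
separators = , ;
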