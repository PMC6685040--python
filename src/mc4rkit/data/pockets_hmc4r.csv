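pocket,position
msh_binding,100
msh_binding,122
msh_binding,126
msh_binding,261
msh_binding,264
msh_binding,284
variant_sensitive,32
variant_sensitive,37
variant_sensitive,125
variant_sensitive,126
variant_sensitive,191
variant_sensitive,194
variant_sensitive,261
variant_sensitive,280
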