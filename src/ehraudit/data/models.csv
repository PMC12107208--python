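name,family,size_billion,mmlu,ceval
Yi-6B,Yi,6,64.11,72
Yi-34B,Yi,34,79.4,81.4
Qwen-1.8B,Qwen,1.8,45.3,56.1
Qwen-7B,Qwen,7,58.2,63.5
Qwen-14B,Qwen,14,66.3,72.1
Llama2-7B,Llama2,7,45.3,
Llama2-13B,Llama2,13,54.8,
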