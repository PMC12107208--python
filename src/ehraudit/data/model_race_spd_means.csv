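model,Black,White,Hispanic,Asian,not_available
Qwen-1.8B,0.6,-20.4,-9.5,-3.1,31.9
Qwen-7B,-3.7,12.5,-13.3,-1.8,5.9
Qwen-14B,2.7,1.3,-12.1,-0.4,8.1
Llama2-7B,7,-6.9,-11.2,6.7,4.1
Llama2-13B,3,6.3,-11.3,-1.8,3.5
Yi-6B,-17,14.4,-13.1,-3.5,18.8
Yi-34B,14.9,-1,-13,-1.5,0.1
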