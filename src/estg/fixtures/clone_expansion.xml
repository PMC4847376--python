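<Program>
  <ExecParams>
    <SimTime>25</SimTime>
    <Seed>1</Seed>
  </ExecParams>
  <FunHandleName></FunHandleName>
  <Rule>
    <Name>Active</Name>
    <InitPop>1</InitPop>
    <Rate>1</Rate>
    <Prod>
      <Products>Active,Active</Products>
      <Prob>ow</Prob>
    </Prod>
    <Prod>
      <Products>Founder</Products>
      <Prob>0.002</Prob>
    </Prod>
    <InternalState>
      <Name>Gen</Name>
      <InitVal>1</InitVal>
      <FuncName>gen_increment</FuncName>
      <DupNum>1</DupNum>
    </InternalState>
    <ConditionalTransition>
      <Condition>Gen &gt; 10</Condition>
      <Transition>Arrested</Transition>
    </ConditionalTransition>
  </Rule>
  <Rule>
    <Name>Founder</Name>
    <InitPop>0</InitPop>
    <Rate>1</Rate>
    <Prod>
      <Products>Active,Active</Products>
      <Prob>1</Prob>
    </Prod>
  </Rule>
  <Rule>
    <Name>Arrested</Name>
    <InitPop>0</InitPop>
    <Rate>0</Rate>
    <Prod>
      <Products>Arrested</Products>
      <Prob>1</Prob>
    </Prod>
  </Rule>
</Program>
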