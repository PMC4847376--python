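<?xml version="1.0" encoding="UTF-8"?>
<!-- Reference schema for the program XML dialect.

     A Program holds execution parameters, an optional global-updater name and
     one Rule per species.  Prob is a probability in [0,1] or the sentinel
     "ow" (one minus the sum of the other probabilities; at most one per
     rule).  Products is a comma-separated list of 0, 1 or 2 species names
     (empty = termination).  Transition is a species name or "{0}" for
     termination.  Condition and non-identifier FuncName texts use the safe
     expression dialect (arithmetic, comparisons, boolean logic, normrnd,
     pop, time). -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="ProbType">
    <xs:restriction base="xs:string">
      <xs:pattern value="ow|[0-9.eE+-]+"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="Program">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="ExecParams">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="SimTime" type="xs:double"/>
              <xs:element name="Seed" type="xs:integer" minOccurs="0"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="FunHandleName" type="xs:string" minOccurs="0"/>
        <xs:element name="Rule" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="Name" type="xs:string"/>
              <xs:element name="InitPop" type="xs:nonNegativeInteger" minOccurs="0"/>
              <xs:element name="Rate" type="xs:double"/>
              <xs:element name="Prod" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Products" type="xs:string"/>
                    <xs:element name="Prob" type="ProbType"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="InternalState" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Name" type="xs:string"/>
                    <xs:element name="InitVal" type="xs:double"/>
                    <xs:element name="FuncName" type="xs:string"/>
                    <xs:element name="DupNum" type="xs:positiveInteger" minOccurs="0"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
              <xs:element name="ConditionalTransition" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="Condition" type="xs:string"/>
                    <xs:element name="Transition" type="xs:string"/>
                  </xs:sequence>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
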